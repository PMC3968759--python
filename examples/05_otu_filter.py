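"""Apply the 1% relative-abundance filter to a toy OTU count table.

An OTU is kept only if it reaches 1% of the reads in at least one sample;
because dropped reads stay in the denominator, the retained abundances sum
to less than 100% — the convention community-composition figures follow.
"""

import pandas as pd

import fefrac as ff

counts = pd.DataFrame(
    {"initial": [4300, 2000, 900, 9, 86],
     "amended": [1500, 2100, 3800, 8, 152]},
    index=["Methanolinea", "Methanosaeta", "Clostridiales", "rare_taxon", "Desulfobulbaceae"],
)
t = ff.OTUTable(counts=counts)

print("Relative abundance (%):")
print(ff.relative_abundance(t).round(2).to_string())

kept = ff.filter_low_abundance(t, threshold_percent=1.0)
print(f"\nAfter the 1% filter: kept {len(kept.otus)} of {len(t.otus)} OTUs "
      f"(dropped: {sorted(set(t.otus) - set(kept.otus))})")

shares = ff.retained_abundance(t, 1.0)
print("\nRetained abundance against original totals (%):")
print(shares.round(2).to_string())
print("\nColumn sums:", shares.sum(axis=0).round(2).to_dict(),
      "- below 100% because the rare OTU's reads remain in the denominator.")
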