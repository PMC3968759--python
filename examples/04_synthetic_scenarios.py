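"""Generate synthetic datasets for the three study-condition presets.

Each preset (initial / unamended / amended) is a fixed mineral assemblage
whose noise-free predictions sit within the replicate scatter of the
corresponding published extraction table. Generating many noisy samples and
re-speciating them shows that the amendment contrast — more amorphous FeII
in the carbon-amended tailings — survives 5% measurement noise.
"""

import io
import warnings

import fefrac as ff
from fefrac.synthetic import generate_dataset, scenario


def speciate_table(meas):
    records = ff.read_measurements(io.StringIO(meas.to_csv(index=False)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ff.speciation_frame([ff.speciate(mt, m) for mt, m in records])


n = 50
print(f"Mean pools over {n} synthetic samples per scenario (noise CV 5%, 3 reps):")
means = {}
for name in ("initial", "unamended", "amended"):
    meas, truth = generate_dataset(scenario(name, noise_cv=0.05, seed=7), n)
    frame = speciate_table(meas)
    means[name] = frame[["fe3_amorphous", "fe3_crystalline",
                         "fe2_crystalline", "fe2_amorphous"]].mean()
    print(f"\n{name} (truth fe2_amorphous = {truth['truth_fe2_amorphous'][0]:.3f}):")
    print(means[name].round(3).to_string())

diff = means["amended"]["fe2_amorphous"] - means["unamended"]["fe2_amorphous"]
print(f"\nAmended minus unamended amorphous FeII: {diff:.3f} wt% —")
print("the amendment signature the speciation chain is built to detect.")
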