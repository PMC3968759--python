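"""Minimal amplicon OTU-table handling: relative abundance + the 1% filter.

Community profiling of the tailings samples uses 16S rRNA gene amplicon
reads clustered into OTUs. Everything upstream (quality control, chimera
removal, clustering, taxonomy assignment) is done by dedicated pipelines and
is out of scope here; this module ingests a generic sample x OTU count table
and applies the standard low-abundance rule: an OTU is retained only if its
relative read abundance reaches the threshold (default 1%) in at least one
sample. Because dropped OTUs are not redistributed, per-sample retained
abundances sum to less than 100% whenever anything was filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["OTUTable", "relative_abundance", "filter_low_abundance", "retained_abundance"]


@dataclass
class OTUTable:
    """Sample x OTU read counts (rows = OTUs, columns = samples).

    ``taxonomy`` optionally maps OTU ids to lineage labels.
    """

    counts: pd.DataFrame
    taxonomy: Optional[dict[str, str]] = field(default=None)

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not (counts.values == counts.values.astype(int)).all():
            raise ValueError("OTU counts must be integers")
        self.counts = counts.astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.index)

    @classmethod
    def from_table(cls, path_or_buf, sep: Optional[str] = None) -> "OTUTable":
        """Read a delimited table: first column OTU id, optional ``taxonomy``
        column, one count column per sample."""
        df = pd.read_csv(path_or_buf, sep=sep, engine="python", index_col=0)
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = df["taxonomy"].to_dict()
            df = df.drop(columns="taxonomy")
        return cls(counts=df, taxonomy=taxonomy)

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        if self.taxonomy is not None:
            df.insert(0, "taxonomy", pd.Series(self.taxonomy))
        return df


def relative_abundance(t: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances in percent (each column sums to 100).

    Raises on any sample with zero total reads (its abundances are
    undefined), naming the offending sample.
    """
    totals = t.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return 100.0 * t.counts / totals


def filter_low_abundance(t: OTUTable, threshold_percent: float = 1.0) -> OTUTable:
    """Drop OTUs whose relative abundance is below threshold in EVERY sample.

    An OTU survives if it reaches ``threshold_percent`` (>=) in at least one
    sample; all sample columns are kept for survivors. The filter is
    idempotent: a second pass recomputes abundances against the smaller
    retained totals, which can only increase them, so every survivor
    survives again and no dropped OTU can return.
    """
    if not 0.0 < threshold_percent < 100.0:
        raise ValueError("threshold_percent must be in (0, 100)")
    rel = relative_abundance(t)
    keep = (rel >= threshold_percent).any(axis=1)
    return OTUTable(
        counts=t.counts.loc[keep],
        taxonomy=(
            {otu: lab for otu, lab in t.taxonomy.items() if keep.get(otu, False)}
            if t.taxonomy is not None
            else None
        ),
    )


def retained_abundance(t: OTUTable, threshold_percent: float = 1.0) -> pd.DataFrame:
    """Abundances of the retained OTUs against the ORIGINAL sample totals.

    This is the quantity community-composition figures report: because
    dropped reads stay in the denominator, each sample column sums to <=
    100%, with equality only when nothing was filtered.
    """
    rel = relative_abundance(t)
    kept = filter_low_abundance(t, threshold_percent)
    return rel.loc[kept.otus]
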