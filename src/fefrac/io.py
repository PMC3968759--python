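"""Delimited-table I/O, configuration and the speciation report.

Measurement tables are UTF-8 delimited text (comma or tab, auto-detected)
with one row per sample. Metadata columns: ``sample_id`` (required),
``treatment``, ``port``, ``eh_mv``, ``solids_fraction``. Each measured
quantity occupies a ``<name>_mean`` / ``<name>_sd`` / ``<name>_n`` triplet;
a missing quantity is simply an empty/absent column. All concentrations are
wt% on an oven-dry solid basis. Quantity names:

    fe_total fe2_ferrozine fe_dcb fe_aod            (mandatory)
    s_avs s_crr p_febound co3_total co3_ca co3_mg   (raw partner elements)
    fe_fes fe_pyrite fe_siderite fe_vivianite       (pre-derived mineral Fe)

The shipped fixture ``table1_table2.csv`` holds the five published reference
samples (initial; unamended ports U2/U3; amended ports A2/A3) typed in
verbatim from the source tables.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from .fractionation import (
    ExtractionMeasurements,
    FeSpeciation,
    Measurement,
    SampleMetadata,
)

__all__ = [
    "QUANTITIES",
    "MANDATORY",
    "Config",
    "read_measurements",
    "load_fixture",
    "write_speciation",
    "speciation_frame",
    "write_report",
]

QUANTITIES = (
    "fe_total",
    "fe2_ferrozine",
    "fe_dcb",
    "fe_aod",
    "s_avs",
    "s_crr",
    "p_febound",
    "co3_total",
    "co3_ca",
    "co3_mg",
    "fe_fes",
    "fe_pyrite",
    "fe_siderite",
    "fe_vivianite",
)
MANDATORY = ("fe_total", "fe2_ferrozine", "fe_dcb", "fe_aod")
META_COLUMNS = ("sample_id", "treatment", "port", "eh_mv", "solids_fraction")


@dataclass
class Config:
    """Run configuration; round-trips losslessly through YAML."""

    ratios_mode: str = "paper"
    clamp: str = "zero"  # "zero" clamps negatives; "strict" raises
    solids_fraction: float = 1.0
    mc_draws: int = 0  # 0 disables Monte-Carlo columns
    seed: int = 0
    interval: float = 0.95
    otu_min_percent: float = 1.0
    selectivity_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratios_mode not in ("paper", "exact"):
            raise ValueError("ratios_mode must be 'paper' or 'exact'")
        if self.clamp not in ("zero", "strict"):
            raise ValueError("clamp must be 'zero' or 'strict'")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        """Short hash of the configuration, for run logging."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def _read_table(path, delimiter: Optional[str] = None) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, engine="python", skipinitialspace=True)


def read_measurements(
    path, delimiter: Optional[str] = None, solids_fraction: float = 1.0
) -> list[tuple[SampleMetadata, ExtractionMeasurements]]:
    """Read and validate a measurement table.

    ``solids_fraction`` is the default for rows that do not carry their own.
    Unknown columns warn; missing mandatory quantities or negative values
    reject with the offending column (and row) named.
    """
    df = _read_table(path, delimiter)
    if df.empty:
        raise ValueError(f"{path}: no records")
    known = set(META_COLUMNS) | {
        f"{q}_{part}" for q in QUANTITIES for part in ("mean", "sd", "n")
    }
    for col in df.columns:
        if col not in known:
            warnings.warn(f"{path}: unknown column {col!r} ignored", UserWarning, stacklevel=2)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'sample_id'")
    for q in MANDATORY:
        if f"{q}_mean" not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{q}_mean'")

    records = []
    for idx, row in df.iterrows():
        meta = SampleMetadata(
            sample_id=str(row["sample_id"]),
            treatment=str(row["treatment"]) if "treatment" in df.columns and not _is_missing(row.get("treatment")) else "custom",
            port=int(row["port"]) if "port" in df.columns and not _is_missing(row.get("port")) else None,
            eh_mv=float(row["eh_mv"]) if "eh_mv" in df.columns and not _is_missing(row.get("eh_mv")) else None,
            solids_fraction=float(row["solids_fraction"])
            if "solids_fraction" in df.columns and not _is_missing(row.get("solids_fraction"))
            else solids_fraction,
        )
        values = {}
        for q in QUANTITIES:
            mean_col = f"{q}_mean"
            if mean_col not in df.columns or _is_missing(row[mean_col]):
                continue
            mean = float(row[mean_col])
            if mean < 0:
                raise ValueError(f"{path}: negative value in row {idx} column {mean_col!r}")
            sd_col, n_col = f"{q}_sd", f"{q}_n"
            sd = float(row[sd_col]) if sd_col in df.columns and not _is_missing(row[sd_col]) else 0.0
            if sd < 0:
                raise ValueError(f"{path}: negative value in row {idx} column {sd_col!r}")
            n = int(row[n_col]) if n_col in df.columns and not _is_missing(row[n_col]) else 1
            values[q] = Measurement(mean, sd, n)
        records.append((meta, ExtractionMeasurements(**values)))
    return records


def load_fixture() -> list[tuple[SampleMetadata, ExtractionMeasurements]]:
    """The five published reference samples shipped with the package."""
    with resources.files("fefrac.data").joinpath("table1_table2.csv").open("r") as fh:
        return read_measurements(fh)


def speciation_frame(results: list[FeSpeciation]) -> pd.DataFrame:
    """One row per sample with every speciation field, warnings serialised."""
    rows = []
    for s in results:
        row = {
            "sample_id": s.sample_id,
            "fe_total": s.fe_total,
            "fe3": s.fe3,
            "fe3_amorphous": s.fe3_amorphous,
            "fe3_crystalline": s.fe3_crystalline,
            "fe2": s.fe2,
            "fe2_crystalline": s.fe2_crystalline,
            "fe2_amorphous": s.fe2_amorphous,
            "fe2_pyrite": s.fe2_components["pyrite"],
            "fe2_siderite": s.fe2_components["siderite"],
            "fe2_vivianite": s.fe2_components["vivianite"],
            "fe2_fes": s.fe2_components["fes"],
            "clamp_residual": s.clamp_residual,
            "warnings": "; ".join(s.warnings),
        }
        rows.append(row)
    columns = [
        "sample_id", "fe_total", "fe3", "fe3_amorphous", "fe3_crystalline",
        "fe2", "fe2_crystalline", "fe2_amorphous", "fe2_pyrite",
        "fe2_siderite", "fe2_vivianite", "fe2_fes", "clamp_residual", "warnings",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_speciation(results: list[FeSpeciation], path, delimiter: str = ",") -> None:
    """Write the speciation table (header-only file for an empty list)."""
    speciation_frame(results).to_csv(path, sep=delimiter, index=False)


def write_report(results: list[FeSpeciation], path, figure_path=None) -> None:
    """Write the speciation table plus a stacked-bar pool figure.

    The figure stacks the four pools (amorphous/crystalline x FeII/FeIII)
    per sample, the standard way endpoint Fe partitions are displayed.
    """
    write_speciation(results, path)
    if not results:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if figure_path is None:
        figure_path = str(path).rsplit(".", 1)[0] + ".png"
    pools = ("fe3_crystalline", "fe3_amorphous", "fe2_crystalline", "fe2_amorphous")
    labels = [s.sample_id for s in results]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(results), 4.0))
    bottom = [0.0] * len(results)
    for pool in pools:
        vals = [getattr(s, pool) for s in results]
        ax.bar(labels, vals, bottom=bottom, label=pool.replace("_", " "))
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_ylabel("Fe (wt% oven-dry)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=120)
    plt.close(fig)
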