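"""File formats and pipeline configuration.

Time courses travel as CSV/TSV with columns ``replicate_id, temperature_C,
time_d, delta13C_permil, sulfide_uM`` (empty sulfide cell = not measured).
ASV counts are TSV with the ASV id in the first column and one column of
integer counts per sample; taxonomy is TSV ``asv_id, class, order, genus``;
sample metadata is TSV ``sample_id, temperature_C, day_d, phase``.

The pipeline configuration is a YAML file with ``isotope``, ``kinetics``,
``stoichiometry`` and ``community`` sections; every constant of the mass
balance and every detection threshold is surfaced there, never hard-coded
downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .isotope import IsotopeStandard, MineralizationContext, R_VPDB
from .kinetics import Timecourse
from .stoichiometry import StoichModel

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_timecourses",
    "write_timecourses",
    "read_asv_table",
    "write_asv_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_sample_metadata",
    "write_sample_metadata",
]

TIMECOURSE_COLUMNS = [
    "replicate_id",
    "temperature_C",
    "time_d",
    "delta13C_permil",
    "sulfide_uM",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the analysis pipeline."""

    # isotope mass balance
    r13_vpdb: float = R_VPDB
    bicarbonate_mM: float = 30.0
    acetate_mM: float = 1.0
    n_labeled: int = 2
    label_purity: float = 0.99
    # kinetics thresholds
    sulfide_detection_uM: float = 10.0
    plateau_tol_permil: float = 50.0
    # stoichiometric coefficients
    o2_per_acetate: float = 2.0
    sulfide_per_acetate: float = 1.0
    hco3_per_acetate: float = 2.0
    # community settings
    order_threshold: float = 0.05
    genus_threshold: float = 0.03
    rarefaction_seed: int = 0

    def __post_init__(self) -> None:
        # constants are validated where they are consumed; catch the obvious here
        self.context()
        self.stoich()
        for name in ("sulfide_detection_uM", "plateau_tol_permil"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        for name in ("order_threshold", "genus_threshold"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {getattr(self, name)!r}")

    def context(self) -> MineralizationContext:
        return MineralizationContext(
            bicarbonate_mM=self.bicarbonate_mM,
            acetate_mM=self.acetate_mM,
            n_labeled=self.n_labeled,
            label_purity=self.label_purity,
            standard=IsotopeStandard(self.r13_vpdb),
        )

    def stoich(self) -> StoichModel:
        return StoichModel(
            o2_per_acetate=self.o2_per_acetate,
            sulfide_per_acetate=self.sulfide_per_acetate,
            hco3_per_acetate=self.hco3_per_acetate,
        )

    def to_yaml(self, path) -> None:
        sections = {
            "isotope": {
                k: getattr(self, k)
                for k in ("r13_vpdb", "bicarbonate_mM", "acetate_mM", "n_labeled", "label_purity")
            },
            "kinetics": {
                k: getattr(self, k) for k in ("sulfide_detection_uM", "plateau_tol_permil")
            },
            "stoichiometry": {
                k: getattr(self, k)
                for k in ("o2_per_acetate", "sulfide_per_acetate", "hco3_per_acetate")
            },
            "community": {
                k: getattr(self, k)
                for k in ("order_threshold", "genus_threshold", "rarefaction_seed")
            },
        }
        Path(path).write_text(yaml.safe_dump(sections, sort_keys=False))


def load_config(path) -> PipelineConfig:
    """Read a sectioned YAML configuration; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    flat: dict = {}
    for section, entries in raw.items():
        if not isinstance(entries, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in entries.items():
            if key not in known:
                raise ValueError(f"unknown config key {section}.{key}")
            flat[key] = value
    return PipelineConfig(**flat)


def _sep_for(path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_timecourses(path) -> list[Timecourse]:
    """Parse a time-course table into one :class:`Timecourse` per replicate."""
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for column in ("time_d", "delta13C_permil"):
        bad = df.index[df[column].isna()]
        if len(bad):
            # +2: one for the header, one for 1-based numbering
            raise ValueError(f"{path}: row {bad[0] + 2}: empty {column} cell")
    out = []
    for rep_id, group in df.groupby("replicate_id", sort=False):
        temps = group["temperature_C"].unique()
        if len(temps) != 1:
            raise ValueError(
                f"{path}: replicate {rep_id!r} has conflicting temperatures {sorted(temps)}"
            )
        group = group.sort_values("time_d")
        out.append(
            Timecourse(
                str(rep_id),
                float(temps[0]),
                group["time_d"].to_numpy(float),
                group["delta13C_permil"].to_numpy(float),
                group["sulfide_uM"].to_numpy(float),
            )
        )
    if not out:
        raise ValueError(f"{path}: no replicates found")
    return out


def write_timecourses(timecourses, path) -> None:
    rows = []
    for tc in timecourses:
        for t, d, s in zip(tc.time_d, tc.delta13C_permil, tc.sulfide_uM):
            rows.append(
                {
                    "replicate_id": tc.replicate_id,
                    "temperature_C": tc.temperature_C,
                    "time_d": t,
                    "delta13C_permil": d,
                    "sulfide_uM": np.nan if np.isnan(s) else s,
                }
            )
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_asv_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: ASV counts must be non-negative integers")
    return df.astype(np.int64)


def write_asv_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="asv_id")


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ("class", "order", "genus") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing taxonomy column(s) {missing}")
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="asv_id")


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ("temperature_C", "day_d", "phase") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    df["phase"] = df["phase"].astype(str)
    return df


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")
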