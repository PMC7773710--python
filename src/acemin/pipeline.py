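"""Pipeline driver: chain segmentation, stoichiometry, statistics and
community metrics into report tables.

``run_pipeline`` consumes parsed replicate time courses (and optionally an
ASV table with taxonomy and sample metadata) and produces a report bundle:

* a per-replicate phase table (phase window, duration, MIN%, amount, rate,
  sulfide, theoretical oxygen) in the layout of a per-experiment overview;
* per-temperature group summaries (mean ± sample SD of rates and oxygen);
* a sulfide/acetate balance table per temperature with the molar ratio and
  the FeS-attributable residual (expected − observed sulfide);
* Shapiro–Wilk and one-way ANOVA on the per-replicate molar ratios;
* when community inputs are given: aggregated relative abundances at order
  and genus rank, rarefied Bray–Curtis dissimilarities, a PCoA embedding
  and the phase-cluster silhouette.

Every detection decision (thresholds, detected windows) is logged at INFO.
Numbers are kept at full precision in the bundle; rounding to one decimal
(half away from zero) happens only when tables are rendered to disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import community as comm
from .group_stats import RatioGroups, one_way_anova, shapiro_wilk
from .io import PipelineConfig
from .kinetics import (
    Timecourse,
    analyze_timecourse,
    round_half_away,
    summarize,
)
from .stoichiometry import expected_sulfide_uM, sulfide_acetate_ratio, theoretical_oxygen_uM

logger = logging.getLogger("acemin")

__all__ = ["ReportBundle", "run_pipeline", "render_report"]


@dataclass
class ReportBundle:
    phase_table: pd.DataFrame
    group_table: pd.DataFrame
    stoich_table: pd.DataFrame
    stats: dict
    community: Optional[dict] = None


def _phase_rows(config: PipelineConfig, timecourses: Sequence[Timecourse]) -> pd.DataFrame:
    ctx = config.context()
    stoich = config.stoich()
    rows = []
    for tc in timecourses:
        results = analyze_timecourse(
            tc, ctx, config.sulfide_detection_uM, config.plateau_tol_permil
        )
        logger.info(
            "replicate %s (%.0f degC): %d phase(s) detected "
            "(sulfide detection %.1f uM, plateau tolerance %.0f permil)",
            tc.replicate_id,
            tc.temperature_C,
            len(results),
            config.sulfide_detection_uM,
            config.plateau_tol_permil,
        )
        for res in results:
            w = res.window
            logger.info(
                "  phase %d: %.4g-%.4g d, %.1f uM at %.2f uM/d",
                w.phase_label, w.t_start_d, w.t_end_d, res.amount_uM, res.rate_uM_per_d,
            )
            rows.append(
                {
                    "temperature_C": tc.temperature_C,
                    "replicate_id": tc.replicate_id,
                    "phase": w.phase_label,
                    "t_start_d": w.t_start_d,
                    "t_end_d": w.t_end_d,
                    "duration_d": w.duration_d,
                    "min_pct": res.min_pct,
                    "amount_uM": res.amount_uM,
                    "rate_uM_per_d": res.rate_uM_per_d,
                    "sulfide_produced_uM": res.sulfide_produced_uM,
                    "sulfide_rate_uM_per_d": res.sulfide_rate_uM_per_d,
                    "theoretical_o2_uM": (
                        theoretical_oxygen_uM(stoich, res.amount_uM)
                        if w.phase_label == 1
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)


def _group_rows(phase_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if phase_table.empty:
        return pd.DataFrame(rows)
    for (temp, phase), grp in phase_table.groupby(["temperature_C", "phase"]):
        summary = summarize(grp["rate_uM_per_d"], temp, phase)
        row = {
            "temperature_C": temp,
            "phase": phase,
            "n": summary.n,
            "rate_mean_uM_per_d": summary.mean,
            "rate_sd_uM_per_d": summary.sd,
        }
        sulf = grp["sulfide_rate_uM_per_d"].dropna()
        if len(sulf):
            s = summarize(sulf, temp, phase)
            row["sulfide_rate_mean_uM_per_d"] = s.mean
            row["sulfide_rate_sd_uM_per_d"] = s.sd
        oxy = grp["theoretical_o2_uM"].dropna()
        if len(oxy):
            o = summarize(oxy, temp, phase)
            row["theoretical_o2_mean_uM"] = o.mean
            row["theoretical_o2_sd_uM"] = o.sd
        rows.append(row)
    return pd.DataFrame(rows)


def _stoich_rows(config: PipelineConfig, phase_table: pd.DataFrame) -> pd.DataFrame:
    stoich = config.stoich()
    rows = []
    if phase_table.empty:
        return pd.DataFrame(rows)
    phase2 = phase_table[phase_table["phase"] == 2]
    for temp, grp in phase2.groupby("temperature_C"):
        amounts = grp["amount_uM"].to_numpy(float)
        sulfides = grp["sulfide_produced_uM"].dropna().to_numpy(float)
        a = summarize(amounts, temp, 2)
        row = {
            "temperature_C": temp,
            "n": a.n,
            "acetate_mineralized_mean_uM": a.mean,
            "acetate_mineralized_sd_uM": a.sd,
        }
        if len(sulfides):
            s = summarize(sulfides, temp, 2)
            expected = expected_sulfide_uM(stoich, a.mean)
            row.update(
                {
                    "sulfide_produced_mean_uM": s.mean,
                    "sulfide_produced_sd_uM": s.sd,
                    "sulfide_acetate_ratio": sulfide_acetate_ratio(s.mean, a.mean),
                    "sulfide_residual_uM": expected - s.mean,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _ratio_stats(phase_table: pd.DataFrame) -> dict:
    stats: dict = {}
    if phase_table.empty:
        return stats
    phase2 = phase_table[phase_table["phase"] == 2].dropna(
        subset=["sulfide_produced_uM"]
    )
    groups: dict = {}
    for temp, grp in phase2.groupby("temperature_C"):
        ratios = [
            sulfide_acetate_ratio(s, a)
            for s, a in zip(grp["sulfide_produced_uM"], grp["amount_uM"])
            if a > 0 and s > 0
        ]
        if ratios:
            groups[temp] = ratios
    if not groups:
        return stats
    ratio_groups = RatioGroups(groups)
    stats["ratio_groups"] = {k: list(v) for k, v in groups.items()}
    pooled = ratio_groups.pooled()
    if 3 <= len(pooled) <= 5000 and np.ptp(pooled) > 0:
        w, p = shapiro_wilk(pooled)
        stats["shapiro_wilk"] = {"W": w, "p_value": p, "n": int(len(pooled))}
    if len(groups) >= 2 and len(pooled) > len(groups):
        try:
            anova = one_way_anova(groups)
            stats["anova"] = {
                "F": anova.f,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p_value": anova.p_value,
            }
        except ValueError as err:
            stats["anova"] = {"error": str(err)}
    return stats


def _community_block(
    config: PipelineConfig,
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    sample_meta: Optional[pd.DataFrame],
) -> dict:
    profiles = comm.relative_abundance(counts)
    block = {
        "by_order": comm.aggregate_taxa(profiles, taxonomy, "order", config.order_threshold),
        "by_genus": comm.aggregate_taxa(profiles, taxonomy, "genus", config.genus_threshold),
    }
    depth = int(counts.sum(axis=0).min())
    logger.info("rarefying %d samples to the minimum depth of %d reads", counts.shape[1], depth)
    rarefied = comm.rarefy(counts, depth, config.rarefaction_seed)
    dm = comm.bray_curtis(rarefied)
    ordination = comm.pcoa(dm)
    block.update({"rarefaction_depth": depth, "bray_curtis": dm, "pcoa": ordination})
    if sample_meta is not None:
        labels = sample_meta.reindex(dm.ids)["phase"].astype(str)
        if labels.notna().all() and labels.nunique() >= 2:
            block["phase_silhouette"] = comm.cluster_separation(dm, labels)
    return block


def run_pipeline(
    config: PipelineConfig,
    timecourses: Sequence[Timecourse],
    asv_counts: Optional[pd.DataFrame] = None,
    taxonomy: Optional[pd.DataFrame] = None,
    sample_meta: Optional[pd.DataFrame] = None,
) -> ReportBundle:
    """Run every analysis stage and collect the report bundle."""
    if not timecourses:
        raise ValueError("need at least one replicate time course")
    phase_table = _phase_rows(config, timecourses)
    bundle = ReportBundle(
        phase_table=phase_table,
        group_table=_group_rows(phase_table),
        stoich_table=_stoich_rows(config, phase_table),
        stats=_ratio_stats(phase_table),
    )
    if asv_counts is not None:
        if taxonomy is None:
            raise ValueError("an ASV table requires a taxonomy map")
        bundle.community = _community_block(config, asv_counts, taxonomy, sample_meta)
    return bundle


def _round_col(frame: pd.DataFrame, columns, ndigits=1) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: round_half_away(v, ndigits) if pd.notna(v) else v
            )
    return out


def render_report(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write the bundle as TSV tables (one decimal, half away from zero)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    phase = _round_col(
        bundle.phase_table,
        [
            "min_pct",
            "amount_uM",
            "rate_uM_per_d",
            "sulfide_produced_uM",
            "sulfide_rate_uM_per_d",
            "theoretical_o2_uM",
        ],
    )
    path = out_dir / "phase_table.tsv"
    phase.to_csv(path, sep="\t", index=False)
    written.append(path)

    group = _round_col(
        bundle.group_table,
        [c for c in bundle.group_table.columns if c.endswith(("_uM_per_d", "_uM"))],
    )
    path = out_dir / "group_summary.tsv"
    group.to_csv(path, sep="\t", index=False)
    written.append(path)

    stoich = _round_col(
        bundle.stoich_table,
        [c for c in bundle.stoich_table.columns if c.endswith("_uM")],
    )
    stoich = _round_col(stoich, ["sulfide_acetate_ratio"], ndigits=2)
    path = out_dir / "sulfide_acetate_balance.tsv"
    stoich.to_csv(path, sep="\t", index=False)
    written.append(path)

    lines = []
    if "shapiro_wilk" in bundle.stats:
        s = bundle.stats["shapiro_wilk"]
        lines.append(
            f"Shapiro-Wilk on pooled molar ratios (n={s['n']}): "
            f"W={s['W']:.4f}, p={s['p_value']:.4f}"
        )
    if "anova" in bundle.stats:
        a = bundle.stats["anova"]
        if "error" in a:
            lines.append(f"one-way ANOVA: {a['error']}")
        else:
            lines.append(
                f"one-way ANOVA on molar ratios: F({a['df_between']},{a['df_within']})"
                f"={a['F']:.2f}, p={a['p_value']:.4f}"
            )
    path = out_dir / "ratio_stats.txt"
    path.write_text("\n".join(lines) + "\n" if lines else "no phase-2 ratios available\n")
    written.append(path)

    if bundle.community is not None:
        block = bundle.community
        for key in ("by_order", "by_genus"):
            path = out_dir / f"abundance_{key}.tsv"
            block[key].to_csv(path, sep="\t", index_label="taxon")
            written.append(path)
        path = out_dir / "bray_curtis.tsv"
        block["bray_curtis"].to_frame().to_csv(path, sep="\t", index_label="sample_id")
        written.append(path)
        path = out_dir / "pcoa_coordinates.tsv"
        ordination = block["pcoa"]
        coords = ordination.coordinates.copy()
        coords.to_csv(path, sep="\t", index_label="sample_id")
        written.append(path)
        summary = [
            f"rarefaction depth: {block['rarefaction_depth']}",
            "proportion explained: "
            + ", ".join(f"{p:.3f}" for p in ordination.proportion_explained[:4]),
        ]
        if "phase_silhouette" in block:
            summary.append(f"phase silhouette: {block['phase_silhouette']:.3f}")
        path = out_dir / "community_summary.txt"
        path.write_text("\n".join(summary) + "\n")
        written.append(path)

    return written
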