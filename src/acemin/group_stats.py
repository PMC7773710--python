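"""Inferential statistics on phase-2 sulfide:acetate molar ratios.

The experimental question is whether incubation temperature changes the
molar ratio of sulfide produced to acetate mineralized in the sulfidogenic
phase.  The ratios are first checked for normality (Shapiro–Wilk) and then
compared across temperature groups with a classic one-way ANOVA.  The ANOVA
here is the standard between/within mean-square decomposition with
df = (k−1, N−k); both the statistic and its degrees of freedom are always
reported so that any non-standard design in an external analysis is visible
rather than silently matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["RatioGroups", "AnovaResult", "one_way_anova", "shapiro_wilk"]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class RatioGroups:
    """Per-temperature lists of per-replicate sulfide:acetate ratios."""

    groups: dict

    def __post_init__(self) -> None:
        for key, values in self.groups.items():
            arr = np.asarray(list(values), dtype=float)
            if arr.size == 0:
                raise ValueError(f"group {key!r} is empty")
            if np.any(arr <= 0):
                raise ValueError(f"group {key!r} contains non-positive ratios")

    def pooled(self) -> np.ndarray:
        return np.concatenate([np.asarray(list(v), float) for v in self.groups.values()])


def one_way_anova(groups: Mapping) -> AnovaResult:
    """Classic one-way ANOVA across groups of observations.

    F = MS_between / MS_within with df_between = k−1 and df_within = N−k;
    the p-value comes from the F distribution.  All-identical observations
    leave F undefined (0/0) and are rejected.
    """
    arrays = [np.asarray(list(v), dtype=float) for v in groups.values()]
    k = len(arrays)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    n_total = sum(a.size for a in arrays)
    if n_total <= k:
        raise ValueError(
            f"need more observations ({n_total}) than groups ({k}) for a within-group df"
        )
    grand_mean = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_between == 0 and ss_within == 0:
        raise ValueError("F undefined: zero between- and within-group variance")
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = float("inf") if ms_within == 0 else float(ms_between / ms_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(f, df_between, df_within, p)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p); requires 3 ≤ n ≤ 5000 and variance > 0."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample (zero variance)")
    result = sps.shapiro(arr)
    return float(result.statistic), float(result.pvalue)
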