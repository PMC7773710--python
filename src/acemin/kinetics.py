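"""Biphasic phase segmentation and rate estimation for microcosm time courses.

Acetate mineralization in these microcosms is biphasic: a short burst of
aerobic oxidation (phase 1) consumes the oxygen accidentally introduced at
setup, δ¹³CO₂ then plateaus, and after a lag a slower sulfidogenic phase
(phase 2) resumes mineralization with concomitant sulfide production.

Segmentation conventions:

* phase 1 runs from the first sample to the first plateau sample — the
  earliest sample after which consecutive δ¹³CO₂ increments stay below
  ``plateau_tol_permil`` while sulfide remains below detection;
* phase 2 runs from the last sample at which sulfide is still below the
  detection limit to the last sample of the series, and is reported only
  when sulfide was actually detected and δ¹³CO₂ rose above the plateau.

The sulfide onset is located by a least-squares fit of a flat/linear-rise/
flat hinge to the sulfide series rather than by thresholding raw readings:
with a methylene-blue detection limit of ~10 μM and typical assay noise of
~20 μM, single-sample threshold crossings misplace the onset far too often,
while the hinge fit reduces to the exact threshold rule on clean data.

Rates are endpoint differences divided by window duration — not regression
slopes — because that is how the per-phase summary tables of such
experiments are constructed.  Rounding (half away from zero, one decimal)
happens only in the reporting layer; all internal math is full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .isotope import DeltaPair, MineralizationContext, amount_mineralized_uM, min_percent

__all__ = [
    "Timecourse",
    "PhaseWindow",
    "PhaseResult",
    "GroupSummary",
    "detect_phases",
    "phase_amount",
    "phase_rate",
    "sulfide_produced",
    "summarize",
    "analyze_timecourse",
    "round_half_away",
]

DEFAULT_SULFIDE_DETECTION_UM = 10.0  # methylene-blue practical limit
DEFAULT_PLATEAU_TOL_PERMIL = 50.0  # per sampling interval


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed rate tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class Timecourse:
    """One replicate's (day, δ¹³CO₂, sulfide) series.

    ``sulfide_uM`` uses NaN for "not measured"; missing sulfide is never
    treated as zero except as the phase-2 window-start baseline.
    """

    replicate_id: str
    temperature_C: float
    time_d: np.ndarray
    delta13C_permil: np.ndarray
    sulfide_uM: np.ndarray

    def __post_init__(self) -> None:
        self.time_d = np.asarray(self.time_d, dtype=float)
        self.delta13C_permil = np.asarray(self.delta13C_permil, dtype=float)
        self.sulfide_uM = np.asarray(self.sulfide_uM, dtype=float)
        n = len(self.time_d)
        if n < 2:
            raise ValueError(
                f"replicate {self.replicate_id!r}: need at least 2 samples, got {n}"
            )
        if len(self.delta13C_permil) != n or len(self.sulfide_uM) != n:
            raise ValueError(
                f"replicate {self.replicate_id!r}: column lengths differ"
            )
        if self.time_d[0] < 0:
            raise ValueError(
                f"replicate {self.replicate_id!r}: first sample time must be >= 0"
            )
        if not np.all(np.diff(self.time_d) > 0):
            raise ValueError(
                f"replicate {self.replicate_id!r}: sample times must be strictly increasing"
            )
        measured = ~np.isnan(self.sulfide_uM)
        if np.any(self.sulfide_uM[measured] < 0):
            raise ValueError(
                f"replicate {self.replicate_id!r}: sulfide concentrations must be >= 0"
            )

    @classmethod
    def from_samples(cls, replicate_id, temperature_C, samples) -> "Timecourse":
        """Build from an iterable of (time_d, delta13C_permil, sulfide_uM|None)."""
        t, d, s = [], [], []
        for row in samples:
            time, delta, sulfide = row
            t.append(time)
            d.append(delta)
            s.append(np.nan if sulfide is None else sulfide)
        return cls(replicate_id, temperature_C, np.array(t), np.array(d), np.array(s))


@dataclass(frozen=True)
class PhaseWindow:
    phase_label: int
    t_start_d: float
    t_end_d: float

    def __post_init__(self) -> None:
        if self.phase_label not in (1, 2):
            raise ValueError(f"phase_label must be 1 or 2, got {self.phase_label!r}")
        if not self.t_end_d > self.t_start_d:
            raise ValueError(
                f"window end ({self.t_end_d}) must exceed start ({self.t_start_d})"
            )

    @property
    def duration_d(self) -> float:
        return self.t_end_d - self.t_start_d


@dataclass(frozen=True)
class PhaseResult:
    """Per-phase mineralization and (phase 2) sulfide accounting."""

    window: PhaseWindow
    min_pct: float
    amount_uM: float
    rate_uM_per_d: float
    sulfide_produced_uM: Optional[float] = None
    sulfide_rate_uM_per_d: Optional[float] = None


@dataclass(frozen=True)
class GroupSummary:
    """mean ± sample SD of one quantity across replicates of a group."""

    temperature_C: float
    phase_label: int
    n: int
    mean: float
    sd: Optional[float]  # absent when n == 1


def _fit_sulfide_onset(t_meas: np.ndarray, s_meas: np.ndarray):
    """Least-squares flat → linear rise → flat hinge on the sulfide series.

    Corner times are restricted to sample times; returns
    ``(corner_time, slope, rise_end_time)`` of the best fit, or ``None``
    when no rising fit exists.  On noise-free piecewise-linear data with
    corners on the sampling grid the fit is exact (SSE = 0).
    """
    m = len(t_meas)
    if m < 2:
        return None
    best = None  # (sse, corner_idx, slope, end_idx)
    for i in range(m - 1):
        for j in range(i + 1, m):
            g = np.clip(t_meas - t_meas[i], 0.0, t_meas[j] - t_meas[i])
            gg = float(g @ g)
            slope = max(float(g @ s_meas) / gg, 0.0)
            resid = s_meas - slope * g
            sse = float(resid @ resid)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, i, slope, j)
    _, i, slope, j = best
    if slope <= 0:
        return None
    return t_meas[i], slope, t_meas[j]


def detect_phases(
    tc: Timecourse,
    sulfide_detection_uM: float = DEFAULT_SULFIDE_DETECTION_UM,
    plateau_tol_permil: float = DEFAULT_PLATEAU_TOL_PERMIL,
) -> list[PhaseWindow]:
    """Segment a replicate time course into 0, 1 or 2 phase windows."""
    if not sulfide_detection_uM > 0:
        raise ValueError(f"sulfide_detection_uM must be positive, got {sulfide_detection_uM!r}")
    if not plateau_tol_permil > 0:
        raise ValueError(f"plateau_tol_permil must be positive, got {plateau_tol_permil!r}")

    t = tc.time_d
    d = tc.delta13C_permil
    s = tc.sulfide_uM
    n = len(t)
    measured = ~np.isnan(s)

    # --- sulfide onset ---------------------------------------------------
    start2_idx = None
    sulfide_detected = bool(np.any(s[measured] >= sulfide_detection_uM))
    if sulfide_detected:
        fit = _fit_sulfide_onset(t[measured], s[measured])
        if fit is not None:
            corner_t, slope, rise_end_t = fit
            fitted = slope * np.clip(t - corner_t, 0.0, rise_end_t - corner_t)
            below = np.flatnonzero(fitted < sulfide_detection_uM)
            start2_idx = int(below[-1]) if len(below) else 0

    # --- phase-1 plateau (searched before the sulfidogenic rise) ---------
    pre_end = start2_idx if start2_idx is not None else n - 1
    increments = np.diff(d[: pre_end + 1])
    plateau_idx = None
    for j in range(pre_end + 1):
        if np.all(increments[j:] < plateau_tol_permil):
            plateau_idx = j
            break

    windows: list[PhaseWindow] = []
    if plateau_idx is not None and plateau_idx > 0:
        windows.append(PhaseWindow(1, float(t[0]), float(t[plateau_idx])))

    # --- phase 2 ----------------------------------------------------------
    if start2_idx is not None and start2_idx < n - 1:
        reference_idx = plateau_idx if windows else start2_idx
        rise_after = float(np.max(d[start2_idx:]) - d[reference_idx])
        if rise_after > plateau_tol_permil:
            windows.append(PhaseWindow(2, float(t[start2_idx]), float(t[-1])))

    return windows


def _sample_index(tc: Timecourse, time_d: float) -> int:
    hits = np.flatnonzero(np.isclose(tc.time_d, time_d, rtol=0.0, atol=1e-9))
    if len(hits) != 1:
        raise ValueError(
            f"replicate {tc.replicate_id!r}: window boundary {time_d} is not a "
            "sample time (no interpolation is performed)"
        )
    return int(hits[0])


def phase_amount(
    tc: Timecourse, window: PhaseWindow, ctx: MineralizationContext
) -> tuple[float, float]:
    """(MIN%, μM acetate) mineralized over a window, via the δ boundary values."""
    i0 = _sample_index(tc, window.t_start_d)
    i1 = _sample_index(tc, window.t_end_d)
    pair = DeltaPair(float(tc.delta13C_permil[i0]), float(tc.delta13C_permil[i1]))
    pct = min_percent(ctx, pair)
    return pct, amount_mineralized_uM(ctx, pct)


def phase_rate(amount_uM: float, window: PhaseWindow) -> float:
    """Endpoint-difference rate: amount ÷ window duration (μM d⁻¹)."""
    duration = window.duration_d
    if not duration > 0:
        raise ValueError(f"window duration must be positive, got {duration!r}")
    return amount_uM / duration


def sulfide_produced(tc: Timecourse, window: PhaseWindow) -> Optional[float]:
    """Sulfide produced within a phase-2 window (μM), or None if unmeasured.

    Maximum measured sulfide inside the window minus the window-start value
    (taken as 0 when the start reading is missing), clamped at zero.
    """
    if window.phase_label != 2:
        raise ValueError("sulfide accounting applies to phase-2 windows only")
    i0 = _sample_index(tc, window.t_start_d)
    i1 = _sample_index(tc, window.t_end_d)
    segment = tc.sulfide_uM[i0 : i1 + 1]
    measured = segment[~np.isnan(segment)]
    if len(measured) == 0:
        return None
    baseline = tc.sulfide_uM[i0]
    if np.isnan(baseline):
        baseline = 0.0
    return max(float(np.max(measured) - baseline), 0.0)


def summarize(
    values: Sequence[float], temperature_C: float, phase_label: int
) -> GroupSummary:
    """Arithmetic mean ± sample SD (n−1) of a replicate group; SD absent at n = 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty replicate group")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return GroupSummary(temperature_C, phase_label, int(arr.size), mean, sd)


def analyze_timecourse(
    tc: Timecourse,
    ctx: MineralizationContext,
    sulfide_detection_uM: float = DEFAULT_SULFIDE_DETECTION_UM,
    plateau_tol_permil: float = DEFAULT_PLATEAU_TOL_PERMIL,
) -> list[PhaseResult]:
    """Detect phases and compute per-phase amounts, rates and sulfide."""
    results = []
    for window in detect_phases(tc, sulfide_detection_uM, plateau_tol_permil):
        pct, amount = phase_amount(tc, window, ctx)
        rate = phase_rate(amount, window)
        produced = None
        produced_rate = None
        if window.phase_label == 2:
            produced = sulfide_produced(tc, window)
            if produced is not None:
                produced_rate = phase_rate(produced, window)
        results.append(
            PhaseResult(window, pct, amount, rate, produced, produced_rate)
        )
    return results
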