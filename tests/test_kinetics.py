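"""Phase segmentation, endpoint rates and replicate summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acemin import (
    PhaseWindow,
    Timecourse,
    analyze_timecourse,
    delta_end_for_percent,
    detect_phases,
    phase_amount,
    phase_rate,
    round_half_away,
    simulate_timecourse,
    sulfide_produced,
    summarize,
)

# (id, amount_uM, duration_d, reported rate) — per-replicate phase rates of
# the temperature experiment, reported at one decimal.  Agreement is checked
# to the printed precision (±0.05, the half-unit of the last digit).
RATE_CELLS = [
    ("12C-1-p1", 119.8, 28, 4.3),
    ("12C-2-p1", 118.2, 7, 16.9),
    ("12C-3-p1", 108.8, 7, 15.5),
    ("12C-1-p2", 931.0, 64, 14.5),
    ("12C-2-p2", 867.2, 101, 8.6),
    ("12C-3-p2", 941.0, 151, 6.2),
    ("25C-1-p1", 138.2, 2, 69.1),
    ("25C-2-p1", 223.8, 2, 111.9),
    ("25C-3-p1", 175.8, 4, 43.9),
    ("25C-1-p2", 801.5, 39, 20.6),
    ("25C-2-p2", 703.2, 39, 18.0),
    ("25C-3-p2", 696.6, 39, 17.9),
    ("38C-1-p1", 176.1, 2, 88.1),
    ("38C-2-p1", 152.8, 3, 50.9),
    ("38C-3-p1", 166.9, 2, 83.4),
    ("38C-1-p2", 811.7, 32, 25.4),
    ("38C-2-p2", 536.1, 32, 16.8),
    ("38C-3-p2", 848.0, 32, 26.5),
    ("45C-1-p1", 137.1, 21, 6.5),
    ("45C-2-p1", 151.7, 28, 5.4),
    ("45C-3-p1", 201.3, 10, 20.1),
    ("45C-3-p2", 647.1, 85, 7.6),
    ("60C-1-p1", 180.5, 3, 60.2),
    ("60C-2-p1", 164.0, 3, 54.7),
    ("60C-3-p1", 198.5, 2, 99.3),
    ("80C-1-p1", 53.8, 7, 7.7),
]

# (id, per-replicate rates, reported mean, reported SD) — group averages.
AVERAGE_CELLS = [
    ("12C-p1", (119.8 / 28, 118.2 / 7, 108.8 / 7), 12.2, 6.9),
    ("12C-p2", (931.0 / 64, 867.2 / 101, 941.0 / 151), 9.8, 4.3),
    ("25C-p1", (138.2 / 2, 223.8 / 2, 175.8 / 4), 75.0, 34.4),
    ("25C-p2", (801.5 / 39, 703.2 / 39, 696.6 / 39), 18.8, 1.5),
    ("38C-p1", (176.1 / 2, 152.8 / 3, 166.9 / 2), 74.1, 20.2),
    ("38C-p2", (811.7 / 32, 536.1 / 32, 848.0 / 32), 22.9, 5.3),
    ("45C-p1", (137.1 / 21, 151.7 / 28, 201.3 / 10), 10.7, 8.2),
    ("45C-p1-n2", (137.1 / 21, 151.7 / 28), 6.0, 0.8),
    ("60C-p1", (180.5 / 3, 164.0 / 3, 198.5 / 2), 71.4, 24.3),
    ("12C-p2-sulfide", (860.0 / 64, 725.5 / 101, 848.7 / 151), 8.75, 4.1),
]


@pytest.mark.parametrize("label, amount, duration, reported", RATE_CELLS, ids=[c[0] for c in RATE_CELLS])
def test_endpoint_rates_reproduce_reported_cells(label, amount, duration, reported):
    window = PhaseWindow(1, 0.0, float(duration))
    assert abs(phase_rate(amount, window) - reported) <= 0.05 + 1e-9


@pytest.mark.parametrize("label, rates, mean, sd", AVERAGE_CELLS, ids=[c[0] for c in AVERAGE_CELLS])
def test_group_summaries_reproduce_reported_averages(label, rates, mean, sd):
    summary = summarize(rates, 0.0, 2)
    assert abs(summary.mean - mean) <= 0.06
    assert abs(summary.sd - sd) <= 0.06


def test_single_replicate_summary_has_no_sd():
    summary = summarize([7.6], 45.0, 2)
    assert summary.mean == pytest.approx(7.6)
    assert summary.sd is None and summary.n == 1


def test_constant_group_has_zero_sd():
    summary = summarize([3.3, 3.3, 3.3], 12.0, 1)
    assert summary.mean == pytest.approx(3.3, rel=1e-12)
    assert summary.sd == pytest.approx(0.0, abs=1e-12)


def test_summarize_rejects_empty_group():
    with pytest.raises(ValueError):
        summarize([], 12.0, 1)


@given(values=st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=30))
@settings(max_examples=100, derandomize=True)
def test_summarize_matches_two_pass_computation(values):
    summary = summarize(values, 0.0, 1)
    mean = sum(values) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
    assert summary.mean == pytest.approx(mean, abs=1e-12, rel=1e-12)
    assert summary.sd == pytest.approx(sd, abs=1e-9, rel=1e-9)


@pytest.mark.parametrize(
    "value, expected",
    [(4.25, 4.3), (-4.25, -4.3), (83.45, 83.5), (14.547, 14.5), (8.75, 8.8)],
)
def test_reporting_rounds_half_away_from_zero(value, expected):
    assert round_half_away(value, 1) == expected


# --- segmentation ----------------------------------------------------------


def _tc(times, deltas, sulfides, temp=25.0, rid="r1"):
    return Timecourse(rid, temp, np.array(times, float), np.array(deltas, float), np.array(sulfides, float))


def test_aerobic_only_series_yields_single_phase1_window():
    tc = _tc([0, 1, 2, 3, 7, 14], [0, 400, 800, 1200, 1200, 1200], [0] * 6)
    windows = detect_phases(tc)
    assert [w.phase_label for w in windows] == [1]
    assert (windows[0].t_start_d, windows[0].t_end_d) == (0.0, 3.0)


def test_sulfide_onset_at_day_63_starts_phase2_window_there():
    times = [0, 3, 7, 14, 28, 42, 63, 70, 84, 98, 112, 127]
    deltas = [0, 600, 1200, 1200, 1200, 1200, 1200, 1750, 2850, 3950, 5050, 6200]
    sulfide = [0, 0, 0, 0, 0, 0, 0, 94, 281, 469, 656, 858]
    windows = detect_phases(_tc(times, deltas, sulfide))
    assert [(w.phase_label, w.t_start_d, w.t_end_d) for w in windows] == [
        (1, 0.0, 7.0),
        (2, 63.0, 127.0),
    ]


def test_inactive_replicate_yields_no_windows():
    tc = _tc([0, 7, 14, 28, 60], [5, 3, 6, 4, 5], [0] * 5)
    assert detect_phases(tc) == []


def test_sulfide_without_renewed_enrichment_yields_no_phase2():
    # sulfide appears but delta13C never rises above the plateau
    tc = _tc([0, 2, 4, 10, 20, 30], [0, 500, 1000, 1000, 1010, 1005], [0, 0, 0, 0, 150, 300])
    assert [w.phase_label for w in detect_phases(tc)] == [1]


def test_timecourse_validation():
    with pytest.raises(ValueError, match="at least 2"):
        _tc([0], [0], [0])
    with pytest.raises(ValueError, match="strictly increasing"):
        _tc([0, 2, 1], [0, 1, 2], [0, 0, 0])
    with pytest.raises(ValueError, match="sulfide"):
        _tc([0, 1], [0, 1], [0, -5])


def test_detect_phases_rejects_bad_thresholds():
    tc = _tc([0, 1, 2], [0, 100, 200], [0, 0, 0])
    with pytest.raises(ValueError):
        detect_phases(tc, sulfide_detection_uM=0.0)
    with pytest.raises(ValueError):
        detect_phases(tc, plateau_tol_permil=-1.0)


# --- windowed amounts ------------------------------------------------------


def test_phase_amount_zero_for_flat_boundaries(ctx):
    tc = _tc([0, 5, 10], [800, 900, 800], [0, 0, 0])
    window = PhaseWindow(1, 0.0, 10.0)
    assert phase_amount(tc, window, ctx) == (0.0, 0.0)


def test_phase_amount_recovers_constructed_target(ctx):
    de = delta_end_for_percent(ctx, -25.0, 12.0)
    tc = _tc([0, 10, 20], [-25.0, de / 2, de], [0, 0, 0])
    pct, amount = phase_amount(tc, PhaseWindow(1, 0.0, 20.0), ctx)
    assert pct == pytest.approx(12.0, rel=1e-12)
    assert amount == pytest.approx(120.0, rel=1e-12)


def test_phase_amount_reference_point(ctx):
    de = delta_end_for_percent(ctx, 0.0, 5.38)
    tc = _tc([0, 7], [0.0, de], [0, 0])
    pct, amount = phase_amount(tc, PhaseWindow(1, 0.0, 7.0), ctx)
    assert pct == pytest.approx(5.38, rel=1e-9)
    assert amount == pytest.approx(53.8, rel=1e-9)
    assert phase_rate(amount, PhaseWindow(1, 0.0, 7.0)) == pytest.approx(7.7, abs=0.05)


def test_phase_amount_rejects_non_sample_boundary(ctx):
    tc = _tc([0, 5, 10], [0, 100, 200], [0, 0, 0])
    with pytest.raises(ValueError, match="not a sample time"):
        phase_amount(tc, PhaseWindow(1, 0.0, 7.0), ctx)


def test_phase_rate_rejects_degenerate_window():
    with pytest.raises(ValueError):
        PhaseWindow(1, 5.0, 5.0)


# --- sulfide accounting ----------------------------------------------------


def test_sulfide_produced_cases():
    window = PhaseWindow(2, 0.0, 30.0)
    constant = _tc([0, 10, 20, 30], [0, 0, 0, 0], [40, 40, 40, 40])
    assert sulfide_produced(constant, window) == 0.0
    rise = _tc([0, 10, 20, 30], [0, 0, 0, 0], [0, 300, 600, 850])
    assert sulfide_produced(rise, window) == 850.0
    offset = _tc([0, 10, 20, 30], [0, 0, 0, 0], [5, 300, 866, 860])
    assert sulfide_produced(offset, window) == 861.0


def test_sulfide_produced_missing_baseline_treated_as_zero():
    tc = _tc([0, 10, 20], [0, 0, 0], [np.nan, 300, 500])
    assert sulfide_produced(tc, PhaseWindow(2, 0.0, 20.0)) == 500.0


def test_sulfide_produced_unmeasured_window_is_absent():
    tc = _tc([0, 10, 20], [0, 0, 0], [np.nan, np.nan, np.nan])
    assert sulfide_produced(tc, PhaseWindow(2, 0.0, 20.0)) is None


def test_sulfide_produced_requires_phase2_window():
    tc = _tc([0, 10], [0, 0], [0, 10])
    with pytest.raises(ValueError):
        sulfide_produced(tc, PhaseWindow(1, 0.0, 10.0))


# --- simulator round trip --------------------------------------------------


def test_noise_free_simulation_is_recovered_exactly(ctx, biphasic_cfg, biphasic_grid):
    tc = simulate_timecourse(biphasic_cfg, biphasic_grid, "round-trip")
    results = analyze_timecourse(tc, ctx)
    assert [(r.window.phase_label, r.window.t_start_d, r.window.t_end_d) for r in results] == [
        (1, 0.0, 2.0),
        (2, 10.0, 50.0),
    ]
    phase1, phase2 = results
    assert phase1.rate_uM_per_d == pytest.approx(100.0, rel=1e-9)
    assert phase1.amount_uM == pytest.approx(biphasic_cfg.phase1_cap_uM, rel=1e-9)
    assert phase2.rate_uM_per_d == pytest.approx(20.0, rel=1e-9)
    assert phase2.sulfide_produced_uM / phase2.amount_uM == pytest.approx(0.9, rel=1e-9)
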