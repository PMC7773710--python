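"""Carbon isotope mass balance for ¹³C-acetate mineralization assays.

Microcosms amended with uniformly ¹³C-labeled acetate release heavy carbon
into the dissolved-inorganic-carbon (DIC) pool as the substrate is oxidized,
so the rise of δ¹³CO₂ between two time points measures how much acetate was
mineralized.  δ values are carried in per mil (‰) against the VPDB
carbonate standard throughout.

Two converters are provided:

* :func:`min_percent` — the linearized single-pool formula used for routine
  reporting.  It treats the bicarbonate pool as fixed and approximates the
  atom fraction by the isotope ratio, which is the convention for reporting
  tracer experiments of this kind.
* :func:`exact_min_percent` — the full non-linear mass balance on ¹³C atom
  fractions, which also accounts for the mineralized carbon itself enlarging
  the DIC pool and for the atom purity of the label.  It serves as the
  independent oracle for the linearized formula; the two agree to ~1% over
  the working range of the assay (δ_end up to ~7000‰).

:func:`delta_end_for_percent` is the exact algebraic inverse of
:func:`min_percent` and is what the forward simulator uses to turn a target
mineralization trajectory into a δ¹³CO₂ time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_VPDB",
    "IsotopeStandard",
    "MineralizationContext",
    "DeltaPair",
    "min_percent",
    "exact_min_percent",
    "amount_mineralized_uM",
    "delta_end_for_percent",
    "atom_fraction",
]

#: Modern ¹³C/¹²C ratio of the Vienna Pee Dee Belemnite carbonate standard.
R_VPDB = 0.0111802

#: Carbon atoms per acetate molecule (CH3COO⁻); all of them end up as CO₂ on
#: complete oxidation, labeled or not.
_CARBONS_PER_ACETATE = 2.0


@dataclass(frozen=True)
class IsotopeStandard:
    """Reference isotope ratio that anchors the δ scale."""

    r13: float = R_VPDB

    def __post_init__(self) -> None:
        if not self.r13 > 0:
            raise ValueError(f"r13 must be positive, got {self.r13!r}")


@dataclass(frozen=True)
class MineralizationContext:
    """Constants of the isotope mass balance for one experimental setup.

    Parameters
    ----------
    bicarbonate_mM
        Dissolved inorganic carbon pool of the medium (mM).  The absolute
        MIN% scale is directly proportional to this pool size.
    acetate_mM
        Amended acetate concentration (mM).
    n_labeled
        Number of ¹³C atoms per substrate molecule; 2 for uniformly labeled
        acetate, 1 for singly labeled.
    label_purity
        Atom fraction ¹³C of the labeled positions (0.99 for a "99 atom %"
        product).  Enters only the exact balance, not the linearized formula.
    """

    bicarbonate_mM: float = 30.0
    acetate_mM: float = 1.0
    n_labeled: int = 2
    label_purity: float = 0.99
    standard: IsotopeStandard = field(default_factory=IsotopeStandard)

    def __post_init__(self) -> None:
        if not self.bicarbonate_mM > 0:
            raise ValueError(
                f"bicarbonate_mM must be positive, got {self.bicarbonate_mM!r}"
            )
        if not self.acetate_mM > 0:
            raise ValueError(f"acetate_mM must be positive, got {self.acetate_mM!r}")
        if self.n_labeled not in (1, 2):
            raise ValueError(f"n_labeled must be 1 or 2, got {self.n_labeled!r}")
        if not 0.5 < self.label_purity <= 1.0:
            raise ValueError(
                f"label_purity must lie in (0.5, 1], got {self.label_purity!r}"
            )


@dataclass(frozen=True)
class DeltaPair:
    """δ¹³CO₂ at the start and end of a mineralization window (‰ vs VPDB)."""

    delta_start_permil: float
    delta_end_permil: float

    def __post_init__(self) -> None:
        for name in ("delta_start_permil", "delta_end_permil"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < -1000.0:
                raise ValueError(f"{name} must be finite and >= -1000 permil, got {value!r}")


def _as_pair(pair) -> DeltaPair:
    if isinstance(pair, DeltaPair):
        return pair
    start, end = pair
    return DeltaPair(float(start), float(end))


def min_percent(ctx: MineralizationContext, pair) -> float:
    """Percent of amended acetate mineralized between two δ¹³CO₂ readings.

    Linearized mass balance on a fixed bicarbonate pool::

        MIN% = 100 * [HCO3-] * R * (δ_end - δ_start)/1000
               / ( n * [acetate] * (1 + R*(1 + δ_start/1000)) )

    with δ in ‰ and R the standard ¹³C/¹²C ratio.  The result is negative
    when δ_end < δ_start (analytical noise); callers decide whether to clip.
    """
    p = _as_pair(pair)
    r = ctx.standard.r13
    numerator = ctx.bicarbonate_mM * r * (p.delta_end_permil - p.delta_start_permil) / 1000.0
    denominator = ctx.n_labeled * ctx.acetate_mM * (
        1.0 + r * (1.0 + p.delta_start_permil / 1000.0)
    )
    return 100.0 * numerator / denominator


def atom_fraction(delta_permil, standard: IsotopeStandard | None = None):
    """¹³C atom fraction x = ¹³C/(¹²C+¹³C) for a δ value (‰).

    ``x = R_δ / (1 + R_δ)`` with ``R_δ = R * (1 + δ/1000)``.  Accepts scalars
    or arrays; strictly increasing in δ, 0 at δ = -1000‰.
    """
    std = standard if standard is not None else IsotopeStandard()
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta < -1000.0):
        raise ValueError("delta_permil below -1000 permil is not physical")
    r_sample = std.r13 * (1.0 + delta / 1000.0)
    x = r_sample / (1.0 + r_sample)
    return float(x) if np.isscalar(delta_permil) else x


def exact_min_percent(ctx: MineralizationContext, pair) -> float:
    """Percent mineralized from the full atom-fraction mass balance.

    Tracks ¹³C atoms explicitly: the DIC pool starts at ``[HCO3-]`` with atom
    fraction ``x(δ_start)`` and every mineralized acetate adds two carbon
    atoms to it — ``n_labeled`` of them at the label purity, the remainder at
    the background fraction.  Solving the balance for the mineralized amount
    ``m`` (mM) gives::

        m = [HCO3-] * (x_e - x_s)
            / ( n*purity + (2 - n)*x_s - 2*x_e )

    This is the independent oracle for :func:`min_percent`; it contains no
    linearization of the δ scale and no fixed-pool approximation.
    """
    p = _as_pair(pair)
    xs = atom_fraction(p.delta_start_permil, ctx.standard)
    xe = atom_fraction(p.delta_end_permil, ctx.standard)
    denominator = (
        ctx.n_labeled * ctx.label_purity
        + (_CARBONS_PER_ACETATE - ctx.n_labeled) * xs
        - _CARBONS_PER_ACETATE * xe
    )
    if denominator <= 0:
        raise ValueError(
            "mass balance degenerate: delta_end implies more label than was added"
        )
    mineralized_mM = ctx.bicarbonate_mM * (xe - xs) / denominator
    return 100.0 * mineralized_mM / ctx.acetate_mM


def amount_mineralized_uM(ctx: MineralizationContext, min_pct: float) -> float:
    """Convert a mineralization percentage to μM of acetate mineralized."""
    if not math.isfinite(min_pct):
        raise ValueError(f"min_pct must be finite, got {min_pct!r}")
    return min_pct / 100.0 * ctx.acetate_mM * 1000.0


def delta_end_for_percent(ctx: MineralizationContext, delta_start_permil, min_pct):
    """Exact algebraic inverse of :func:`min_percent`.

    Returns the δ¹³CO₂ endpoint (‰) that corresponds to mineralizing
    ``min_pct`` percent of the amended acetate starting from
    ``delta_start_permil``.  Vectorized over ``min_pct`` for the simulator.
    """
    r = ctx.standard.r13
    pct = np.asarray(min_pct, dtype=float)
    correction = ctx.n_labeled * ctx.acetate_mM * (
        1.0 + r * (1.0 + np.asarray(delta_start_permil, dtype=float) / 1000.0)
    )
    delta_end = delta_start_permil + pct / 100.0 * correction * 1000.0 / (
        ctx.bicarbonate_mM * r
    )
    return float(delta_end) if np.isscalar(min_pct) else delta_end
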