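"""Electron-acceptor stoichiometry of acetate mineralization.

Aerobic phase: complete oxidation of acetate consumes two moles of oxygen
per mole of acetate (CH3COO⁻ + 2 O₂ → 2 HCO3⁻-equivalents), so the oxygen
demand implied by an observed aerobic mineralization amount is simply twice
that amount.  Sulfidogenic phase: dissimilatory sulfate reduction oxidizes
acetate completely via

    CH3COO⁻ + SO4²⁻ → 2 HCO3⁻ + HS⁻

yielding one mole of sulfide and two of bicarbonate per mole of acetate.
The sulfide:acetate molar ratio therefore has a theoretical value of 1;
observed ratios below 1 are usually attributed to FeS precipitation, which
this module reports as a residual (expected − observed) rather than models.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StoichModel",
    "theoretical_oxygen_uM",
    "expected_sulfide_uM",
    "sulfide_acetate_ratio",
]


@dataclass(frozen=True)
class StoichModel:
    """Molar coefficients per mole of acetate completely oxidized."""

    o2_per_acetate: float = 2.0
    sulfide_per_acetate: float = 1.0
    hco3_per_acetate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("o2_per_acetate", "sulfide_per_acetate", "hco3_per_acetate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")


def theoretical_oxygen_uM(model: StoichModel, acetate_uM: float) -> float:
    """Oxygen demand (μM) of aerobically mineralizing ``acetate_uM`` of acetate."""
    if acetate_uM < 0:
        raise ValueError(f"acetate_uM must be >= 0, got {acetate_uM!r}")
    return acetate_uM * model.o2_per_acetate


def expected_sulfide_uM(model: StoichModel, acetate_uM: float) -> float:
    """Sulfide (μM) expected from sulfate-reducing oxidation of ``acetate_uM``."""
    if acetate_uM < 0:
        raise ValueError(f"acetate_uM must be >= 0, got {acetate_uM!r}")
    return acetate_uM * model.sulfide_per_acetate


def sulfide_acetate_ratio(sulfide_uM: float, acetate_uM: float) -> float:
    """Observed sulfide-produced : acetate-mineralized molar ratio."""
    if not acetate_uM > 0:
        raise ValueError(f"acetate_uM must be positive, got {acetate_uM!r}")
    return sulfide_uM / acetate_uM
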