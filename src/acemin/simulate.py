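"""Forward simulation of microcosm time courses and phase-structured communities.

The time-course generator reproduces the biphasic structure of the assay:
cumulative mineralization rises piecewise-linearly — an aerobic burst at
``phase1_rate`` until the oxygen inventory is exhausted (cap =
o2 / o2-per-acetate), a plateau through ``lag_d`` days, then a sulfidogenic
rise at ``phase2_rate`` until the amended acetate is gone.  δ¹³CO₂ is the
exact inverse of the reporting mass balance applied phase-wise (each phase
referenced to its own starting δ, matching how per-phase windows are read
out), and sulfide tracks the phase-2 mineralized amount scaled by
``sulfide_yield``.  Piecewise-linear segments — not logistic or Monod
curves — are deliberate: phase rates are defined as endpoint slopes, so a
noise-free simulation is recovered exactly by the detection pipeline.

Noise is additive Gaussian, independent across time points, on both δ and
sulfide (sulfide clamped at zero); defaults of 100‰ / 20 μM reflect the
replicate scatter visible in this kind of assay.

Community tables are drawn per sample from a Dirichlet-multinomial around a
condition profile (aerobe-dominated phase 1, diverse sulfidogenic phase 2,
spore-former-dominated 45–60°C, plus the anaerobic inoculum).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .isotope import MineralizationContext, delta_end_for_percent
from .kinetics import Timecourse
from .stoichiometry import StoichModel

__all__ = [
    "SimulationConfig",
    "simulate_timecourse",
    "default_time_grid",
    "load_presets",
    "preset_config",
    "CommunityProfile",
    "CommunitySimConfig",
    "simulate_asv_counts",
    "default_community_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated microcosm replicate."""

    ctx: MineralizationContext = field(default_factory=MineralizationContext)
    stoich: StoichModel = field(default_factory=StoichModel)
    temperature_C: float = 25.0
    o2_uM: float = 358.5
    phase1_rate_uM_per_d: float = 75.0
    lag_d: float = 7.6
    phase2_rate_uM_per_d: float = 18.8
    sulfide_yield: float = 0.9
    delta_start_permil: float = -25.0
    noise_sd_delta_permil: float = 100.0
    noise_sd_sulfide_uM: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.o2_uM < 0:
            raise ValueError(f"o2_uM must be >= 0, got {self.o2_uM!r}")
        for name in ("phase1_rate_uM_per_d", "phase2_rate_uM_per_d", "lag_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0 <= self.sulfide_yield <= 1.1:
            raise ValueError(f"sulfide_yield must lie in [0, 1.1], got {self.sulfide_yield!r}")
        for name in ("noise_sd_delta_permil", "noise_sd_sulfide_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    # --- derived quantities ----------------------------------------------
    @property
    def acetate_total_uM(self) -> float:
        return self.ctx.acetate_mM * 1000.0

    @property
    def phase1_cap_uM(self) -> float:
        """Aerobically mineralizable acetate: oxygen inventory / O₂ demand."""
        if self.phase1_rate_uM_per_d <= 0:
            return 0.0
        return min(self.o2_uM / self.stoich.o2_per_acetate, self.acetate_total_uM)

    @property
    def t_phase1_end_d(self) -> float:
        if self.phase1_cap_uM <= 0:
            return 0.0
        return self.phase1_cap_uM / self.phase1_rate_uM_per_d

    @property
    def t_phase2_start_d(self) -> float:
        return self.t_phase1_end_d + self.lag_d

    @property
    def t_exhaustion_d(self) -> float:
        remaining = self.acetate_total_uM - self.phase1_cap_uM
        if self.phase2_rate_uM_per_d <= 0 or remaining <= 0:
            return float("inf")
        return self.t_phase2_start_d + remaining / self.phase2_rate_uM_per_d


def cumulative_mineralized_uM(cfg: SimulationConfig, times) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free cumulative (phase-1, phase-2) mineralized acetate (μM)."""
    t = np.asarray(times, dtype=float)
    cap = cfg.phase1_cap_uM
    cum1 = np.minimum(cfg.phase1_rate_uM_per_d * np.clip(t, 0.0, None), cap)
    remaining = cfg.acetate_total_uM - cap
    cum2 = np.minimum(
        cfg.phase2_rate_uM_per_d * np.clip(t - cfg.t_phase2_start_d, 0.0, None),
        max(remaining, 0.0),
    )
    return cum1, cum2


def simulate_timecourse(
    cfg: SimulationConfig, times: Sequence[float], replicate_id: str = "sim"
) -> Timecourse:
    """Simulate one replicate's (day, δ¹³CO₂, sulfide) series on a time grid."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("time grid must not be empty")
    if t.size < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("time grid must contain >= 2 strictly increasing times")

    cum1, cum2 = cumulative_mineralized_uM(cfg, t)
    total = cfg.acetate_total_uM
    pct1 = 100.0 * cum1 / total
    pct2 = 100.0 * cum2 / total

    cap_pct = 100.0 * cfg.phase1_cap_uM / total
    delta_plateau = delta_end_for_percent(cfg.ctx, cfg.delta_start_permil, cap_pct)
    in_phase1 = cum1 < cfg.phase1_cap_uM if cfg.phase1_cap_uM > 0 else np.zeros_like(t, bool)
    # phase-wise δ: each phase referenced to its own starting value, the
    # same convention the windowed read-out uses
    delta = np.where(
        in_phase1,
        delta_end_for_percent(cfg.ctx, cfg.delta_start_permil, pct1),
        delta_end_for_percent(cfg.ctx, delta_plateau, pct2),
    )
    sulfide = cfg.sulfide_yield * cum2

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd_delta_permil > 0:
        delta = delta + rng.normal(0.0, cfg.noise_sd_delta_permil, size=t.shape)
    if cfg.noise_sd_sulfide_uM > 0:
        sulfide = sulfide + rng.normal(0.0, cfg.noise_sd_sulfide_uM, size=t.shape)
    sulfide = np.clip(sulfide, 0.0, None)
    delta = np.maximum(delta, -999.9)

    return Timecourse(replicate_id, cfg.temperature_C, t, delta, sulfide)


def default_time_grid(cfg: SimulationConfig, horizon_d: float = 178.0) -> np.ndarray:
    """Sampling schedule bracketing the model breakpoints.

    Dense early sampling (the aerobic burst is over within days), then
    regular sampling until acetate exhaustion or ``horizon_d``; model
    breakpoints are included so noise-free runs are segmented exactly.
    """
    end = cfg.t_exhaustion_d
    if not np.isfinite(end):
        end = horizon_d
    end = min(end, horizon_d)
    step = max(1.0, round(end / 30.0))
    points = {0.0, end}
    points.update(np.arange(0.0, end, step))
    points.update([1.0, 2.0, 3.0, 5.0, 7.0])
    for bp in (cfg.t_phase1_end_d, cfg.t_phase2_start_d):
        if 0 < bp < end:
            points.add(float(bp))
    return np.array(sorted(p for p in points if p <= end))


def load_presets() -> dict[int, dict]:
    """Per-temperature forward-model presets shipped with the package."""
    text = (
        importlib.resources.files("acemin").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)


def preset_config(temperature_C: int, seed: int = 0, noise: bool = True, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` for one of the six incubation temperatures."""
    presets = load_presets()
    key = int(temperature_C)
    if key not in presets:
        raise ValueError(f"no preset for {temperature_C!r}; available: {sorted(presets)}")
    params = dict(presets[key])
    cfg = SimulationConfig(temperature_C=float(key), seed=seed, **params)
    if not noise:
        cfg = replace(cfg, noise_sd_delta_permil=0.0, noise_sd_sulfide_uM=0.0)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityProfile:
    """Taxon-probability vector for one (phase, temperature) condition."""

    name: str
    temperature_C: float
    phase: str  # "1", "2" or "inoculum"
    day_d: float
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"profile {self.name!r}: probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class CommunitySimConfig:
    """Dirichlet-multinomial model of phase-structured 16S count tables."""

    taxa: tuple
    taxonomy: pd.DataFrame  # index: ASV id; columns: class, order, genus
    profiles: tuple
    dispersion: float = 200.0  # Dirichlet concentration; inf = pure multinomial
    depth: int = 20000  # reads per sample
    n_samples: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dispersion > 0:
            raise ValueError(f"dispersion must be positive, got {self.dispersion!r}")
        if not self.depth > 0:
            raise ValueError(f"depth must be positive, got {self.depth!r}")
        if not self.n_samples > 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples!r}")
        n = len(self.taxa)
        for profile in self.profiles:
            if len(profile.probabilities) != n:
                raise ValueError(
                    f"profile {profile.name!r} has {len(profile.probabilities)} "
                    f"probabilities for {n} taxa"
                )
        missing = [t for t in self.taxa if t not in self.taxonomy.index]
        if missing:
            raise ValueError(f"taxa missing from the taxonomy map: {missing}")


def simulate_asv_counts(cfg: CommunitySimConfig):
    """Draw an (AsvTable-style counts, sample metadata) pair from the model.

    Per sample: a Dirichlet draw around the condition profile (concentration
    = dispersion × p) followed by a multinomial of ``depth`` reads; infinite
    dispersion degenerates to a pure multinomial.  Deterministic under seed.
    """
    rng = np.random.default_rng(cfg.seed)
    columns = {}
    meta_rows = []
    for profile in cfg.profiles:
        p = profile.probabilities
        support = p > 0
        for i in range(cfg.n_samples):
            sample_id = f"{profile.name}_r{i + 1}"
            if np.isinf(cfg.dispersion):
                probs = p[support]
            else:
                probs = rng.dirichlet(cfg.dispersion * p[support])
            counts = np.zeros(len(p), dtype=np.int64)
            counts[support] = rng.multinomial(cfg.depth, probs)
            columns[sample_id] = counts
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "temperature_C": profile.temperature_C,
                    "day_d": profile.day_d,
                    "phase": profile.phase,
                }
            )
    counts = pd.DataFrame(columns, index=list(cfg.taxa))
    counts.index.name = "asv_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta


# (class, order, genus) catalogue of the taxa the model community is built
# from: mesophilic aerobes, spore-forming thermophiles, sulfate reducers and
# the fermentative/anaerobic background of the inoculum.
_TAXA_CATALOG = {
    "asv_anpr": ("Alphaproteobacteria", "Rhizobiales", "Allorhizobium-Neorhizobium-Pararhizobium-Rhizobium"),
    "asv_thiobacillus": ("Gammaproteobacteria", "Betaproteobacteriales", "Thiobacillus"),
    "asv_sulfurovum": ("Campylobacteria", "Campylobacterales", "Sulfurovum"),
    "asv_bacillus": ("Bacilli", "Bacillales", "Bacillus"),
    "asv_aeribacillus": ("Bacilli", "Bacillales", "Aeribacillus"),
    "asv_brevibacillus": ("Bacilli", "Bacillales", "Brevibacillus"),
    "asv_planifilum": ("Bacilli", "Bacillales", "Planifilum"),
    "asv_desulfoprunum": ("Deltaproteobacteria", "Desulfobacterales", "Desulfoprunum"),
    "asv_desulfurivibrio": ("Deltaproteobacteria", "Desulfobacterales", "Desulfurivibrio"),
    "asv_desulfovibrio": ("Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrio"),
    "asv_desulfatiglans": ("Deltaproteobacteria", "Desulfarculales", "Desulfatiglans"),
    "asv_desulfobacca": ("Deltaproteobacteria", "Syntrophobacterales", "Desulfobacca"),
    "asv_desulfotomaculum": ("Clostridia", "Clostridiales", "Desulfotomaculum"),
    "asv_desulfurispora": ("Clostridia", "Clostridiales", "Desulfurispora"),
    "asv_pelolinea": ("Anaerolineae", "Anaerolineales", "Pelolinea"),
    "asv_anaerolineaceae": ("Anaerolineae", "Anaerolineales", "uncultured Anaerolineaceae"),
    "asv_bsv26": ("Ignavibacteria", "Ignavibacteriales", "BSV26"),
    "asv_lentimicrobium": ("Bacteroidia", "Sphingobacteriales", "Lentimicrobium"),
    "asv_paludibacter": ("Bacteroidia", "Bacteroidales", "Paludibacter"),
    "asv_spirochaetaceae": ("Spirochaetia", "Spirochaetales", "uncultured Spirochaetaceae"),
}

# Raw (unnormalized) weights per condition, keyed by ASV id.
_PROFILE_WEIGHTS = {
    "inoculum": {
        "asv_pelolinea": 0.113, "asv_anaerolineaceae": 0.12, "asv_desulfobacca": 0.06,
        "asv_desulfatiglans": 0.06, "asv_bsv26": 0.07, "asv_desulfotomaculum": 0.05,
        "asv_desulfurispora": 0.04, "asv_spirochaetaceae": 0.05, "asv_lentimicrobium": 0.04,
        "asv_paludibacter": 0.03, "asv_desulfovibrio": 0.05, "asv_desulfoprunum": 0.03,
        "asv_desulfurivibrio": 0.03, "asv_sulfurovum": 0.016, "asv_anpr": 0.0016,
        "asv_thiobacillus": 0.0006, "asv_bacillus": 0.02,
    },
    # aerobe-dominated first phase at 12-38 degC
    "phase1_meso": {
        "asv_anpr": 0.75, "asv_thiobacillus": 0.12, "asv_sulfurovum": 0.03,
        "asv_bacillus": 0.04, "asv_pelolinea": 0.015, "asv_anaerolineaceae": 0.015,
        "asv_bsv26": 0.01, "asv_spirochaetaceae": 0.01, "asv_desulfatiglans": 0.01,
    },
    # diverse sulfidogenic second phase at 12-38 degC
    "phase2_meso": {
        "asv_anpr": 0.08, "asv_thiobacillus": 0.05, "asv_sulfurovum": 0.02,
        "asv_desulfoprunum": 0.12, "asv_desulfovibrio": 0.04, "asv_desulfatiglans": 0.04,
        "asv_desulfurivibrio": 0.03, "asv_desulfotomaculum": 0.06, "asv_desulfurispora": 0.03,
        "asv_lentimicrobium": 0.08, "asv_paludibacter": 0.04, "asv_spirochaetaceae": 0.09,
        "asv_pelolinea": 0.08, "asv_anaerolineaceae": 0.08, "asv_bsv26": 0.12,
        "asv_desulfobacca": 0.02, "asv_bacillus": 0.01,
    },
    # spore-former-dominated aerobic phase at 45-60 degC
    "phase1_thermo": {
        "asv_bacillus": 0.30, "asv_aeribacillus": 0.18, "asv_brevibacillus": 0.14,
        "asv_planifilum": 0.08, "asv_spirochaetaceae": 0.12, "asv_sulfurovum": 0.05,
        "asv_pelolinea": 0.03, "asv_anaerolineaceae": 0.03, "asv_desulfatiglans": 0.02,
        "asv_anpr": 0.03, "asv_desulfobacca": 0.02,
    },
}

# (profile key, temperature, phase label, sacrifice day) of the shipped design
_DEFAULT_CONDITIONS = [
    ("inoculum", float("nan"), "inoculum", 0.0),
    ("phase1_meso", 12.0, "1", 7.0),
    ("phase2_meso", 12.0, "2", 178.0),
    ("phase1_meso", 25.0, "1", 4.0),
    ("phase2_meso", 25.0, "2", 36.0),
    ("phase1_meso", 38.0, "1", 4.0),
    ("phase2_meso", 38.0, "2", 36.0),
    ("phase1_thermo", 45.0, "1", 7.0),
    ("phase1_thermo", 60.0, "1", 7.0),
]


def default_taxonomy() -> pd.DataFrame:
    frame = pd.DataFrame.from_dict(
        _TAXA_CATALOG, orient="index", columns=["class", "order", "genus"]
    )
    frame.index.name = "asv_id"
    return frame


def _profile_vector(weights: dict, taxa) -> np.ndarray:
    p = np.array([weights.get(t, 0.0) for t in taxa], dtype=float)
    return p / p.sum()


def default_community_config(
    seed: int = 0, dispersion: float = 200.0, depth: int = 20000, n_samples: int = 3
) -> CommunitySimConfig:
    """The shipped succession design: inoculum plus per-temperature phases."""
    taxonomy = default_taxonomy()
    taxa = tuple(taxonomy.index)
    profiles = []
    for key, temp, phase, day in _DEFAULT_CONDITIONS:
        name = key if key == "inoculum" else f"T{int(temp)}_{key}"
        profiles.append(
            CommunityProfile(
                name=name,
                temperature_C=temp,
                phase=phase,
                day_d=day,
                probabilities=_profile_vector(_PROFILE_WEIGHTS[key], taxa),
            )
        )
    return CommunitySimConfig(
        taxa=taxa,
        taxonomy=taxonomy,
        profiles=tuple(profiles),
        dispersion=dispersion,
        depth=depth,
        n_samples=n_samples,
        seed=seed,
    )
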