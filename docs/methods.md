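# Methods

## Isotope mass balance

The assay follows mineralization of 1 mM uniformly ¹³C-labeled acetate
(99 atom %, so both carbons carry the label) into the dissolved inorganic
carbon (DIC) pool of a bicarbonate-buffered medium, read out as δ¹³CO₂ in
per mil against VPDB (R_VPDB = 0.0111802, configurable). Two converters are
implemented.

The **reporting formula** (`min_percent`) is the conventional linearized
single-pool balance: the ¹³C excess transferred into a fixed pool
[HCO₃⁻]·R·Δδ/1000, normalized by the labeled carbon added,
n·[acetate]·(1 + R·(1 + δ_start/1000)). δ values enter in ‰ and are divided
by 1000 inside both the numerator and the correction term; this is the only
reading under which a ~6000‰ rise corresponds to near-complete turnover of
1 mM acetate against a ~30 mM pool, which the package asserts as a
self-consistency check (computed: 99.5 %).

The **exact balance** (`exact_min_percent`) works on atom fractions
x(δ) = R_δ/(1+R_δ) and additionally accounts for the fact that every
mineralized acetate adds its two carbon atoms to the DIC pool — n of them
at the label purity, the remainder at the background fraction. Solving the
¹³C budget for the mineralized amount m gives

    m = [HCO₃⁻] · (x_e − x_s) / ( n·purity + (2−n)·x_s − 2·x_e ).

Neglecting the pool growth is *not* a second-order effect here: at
δ_end = 7000‰ a fixed-pool atom-fraction balance deviates from the
linearized formula by ~8 %, while the full balance above stays within
~1.1 % of it across δ_end ≤ 7000‰ — the two linearization errors (δ-scale
and pool growth) nearly cancel, which is why the simple reporting formula
works as well as it does. The 3 % agreement bound asserted in the tests is
therefore a property of the full balance, and `exact_min_percent`
implements that balance.

`delta_end_for_percent` is the exact algebraic inverse of the reporting
formula; the forward simulator uses it so that a simulated trajectory reads
back to the configured mineralization exactly. Negative MIN% (δ_end below
δ_start, i.e. analytical noise) is returned unclipped so that noise
structure survives round trips.

Defaults: [HCO₃⁻] = 30 mM (a typical bicarbonate-buffered freshwater
medium; the value scales all absolute MIN% results and is always
configurable), [acetate] = 1 mM, n = 2, purity = 0.99.

## Phase segmentation and rates

A replicate time course is segmented into at most two windows:

* **Phase 1 (oxic)** runs from the first sample to the first plateau
  sample — the earliest sample after which consecutive δ¹³CO₂ increments
  stay below `plateau_tol_permil` (default 50‰ per sampling interval)
  while sulfide remains below detection. A series that is flat from the
  start yields no phase-1 window (the inactive pattern).
* **Phase 2 (sulfidogenic)** runs from the last sample at which sulfide is
  below the detection limit (default 10 μM, the practical limit of the
  methylene-blue assay) to the last sample, and is emitted only when
  sulfide was actually detected *and* δ¹³CO₂ rose above the plateau by more
  than the tolerance.

**Sulfide onset.** The phase-2 start is not read off raw threshold
crossings. With detection at 10 μM and a realistic sulfide noise SD of
20 μM, a pre-onset reading exceeds the detection limit with probability
~0.31, so any single-sample rule misplaces the window start in roughly one
run in ten — enough to spoil rate recovery. Instead the sulfide series is
fit by least squares with a flat → linear-rise → flat hinge (corner times
restricted to sample times; closed-form slope per corner pair; smallest
SSE wins, earliest corner on ties), and the window starts at the last
sample time where the *fitted* curve is below detection. On noise-free
piecewise-linear data the fit is exact (SSE = 0) and the rule reduces to
the plain threshold convention; under the stated noise the Monte-Carlo
recovery criterion (phase-2 rate within 10 % in ≥ 95 % of 200 seeded runs)
passes with margin.

**Rates** are endpoint differences divided by window duration, not
regression slopes: that is the arithmetic of the per-phase summary tables
this pipeline reproduces (e.g. 931.0 μM / 64 d = 14.5 μM d⁻¹), and it makes
zero-noise recovery of simulator parameters exact. Window boundaries must
be sample times — no interpolation. Group summaries are arithmetic mean ±
sample SD (n−1), SD omitted at n = 1. Rounding (half away from zero, one
decimal; ratios two decimals) happens only in the report renderer; all
internal math is double precision.

Missing sulfide readings are "not measured", never zero — except as the
phase-2 window-start baseline, where an unmeasured start is taken as 0.
Sulfide produced in a window is max-within-window minus baseline, clamped
at zero.

## Stoichiometry and statistics

Theoretical oxygen demand uses 2 mol O₂ per mol acetate (complete
oxidation); sulfate reduction yields 1 mol HS⁻ and 2 mol HCO₃⁻ per mol
acetate. All three coefficients are configurable. Molar ratios are computed
from replicate-group means for the balance table, and per replicate for the
statistics; the FeS-attributable deficit is reported as a residual
(expected − observed sulfide), not modeled.

The ratio statistics are a Shapiro–Wilk test on the pooled per-replicate
ratios (delegated to scipy) and a standard one-way ANOVA (own sum-of-squares
decomposition, p-value from the F distribution, cross-checked against
scipy's implementation at 1e-10). The ANOVA always reports its degrees of
freedom (k−1, N−k) alongside F so that comparisons against analyses with
non-standard designs stay transparent; no post-hoc tests or corrections are
applied.

## Community metrics

Inputs are ASV × sample count tables with a taxonomy map (class / order /
genus) and per-sample metadata. Relative abundances are per-sample
fractions; aggregation at a rank keeps a taxon if it reaches the threshold
in **at least one** sample (max-over-samples — the convention that matches
stacked-bar figures; a mean-over-samples reading would bucket taxa that
spike in single samples) and sums the rest into "Others", conserving column
totals exactly. Defaults: 5 % at order rank, 3 % at genus rank.

Rarefaction is one multivariate hypergeometric draw per sample (subsampling
without replacement, numpy Generator) to the minimum sample depth, with a
mandatory seed; no repeated-rarefaction averaging. Bray–Curtis is computed
with scipy on rarefied counts for ordination (any non-negative profiles are
accepted). PCoA is classical metric scaling — double-centering of −½D²,
symmetric eigendecomposition — with negative eigenvalues clamped to zero,
reported, and excluded from coordinates (no Lingoes/Cailliez correction);
scikit-bio's implementation serves as an independent oracle in the tests.
Phase-cluster separation is the mean silhouette on the dissimilarity
matrix (scikit-learn).

## Forward simulator

Cumulative mineralization is piecewise linear: an aerobic rise at
`phase1_rate` capped at o2_uM / (O₂ per acetate) — tying the simulator to
the stoichiometry module — a plateau of `lag_d` days, then a sulfidogenic
rise at `phase2_rate` until the amendment is exhausted. δ¹³CO₂ is obtained
by inverting the reporting formula *phase-wise* (each phase referenced to
its own starting δ, exactly how the windowed read-out evaluates it), so a
noise-free run is recovered to 1e-9 when the sampling grid contains the
phase corners; sulfide is `sulfide_yield` × phase-2 mineralized. Noise is
additive Gaussian, independent across time points (no autocorrelation),
default SDs 100‰ on δ and 20 μM on sulfide; sulfide is clamped at 0.
Logistic/Monod curvature is deliberately out of scope: the quantities of
interest are endpoint slopes.

Per-temperature presets (12–80 °C) encode the study conditions: oxygen
inventories of ~230–360 μM (from the observed aerobic caps), phase-1 rates
of 11–75 μM d⁻¹, phase-2 rates of 7.6–22.9 μM d⁻¹, sulfide yields of
0.71–1.01, with 60 °C aerobic-only and 80 °C inactive. The default sampling
grid is dense over the first week and then regular (≥1 d) to exhaustion or
178 d.

Community tables are Dirichlet-multinomial: per sample, a Dirichlet draw
with concentration `dispersion` × profile (default 200 — tight but visibly
dispersed profiles; ∞ degenerates to a pure multinomial) followed by a
multinomial of `depth` reads (default 20 000). The shipped design has four
profiles over a 20-taxon catalogue: a diverse anaerobic inoculum, an
ANPR/Thiobacillus-dominated mesophilic phase 1, a diverse sulfidogenic
phase 2 (Desulfoprunum, Desulfotomaculum, Ignavibacteria, Spirochaetaceae,
Anaerolineae, …) and a Bacilli-dominated 45–60 °C phase 1.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the assay — biphasic kinetics,
stoichiometric sulfide coupling, phase-partitioned communities — so passing
tests demonstrate that the pipeline's estimators are unbiased and exact on
data generated by their own model class, and robust at the stated noise.
They do not validate behaviors absent from the model: autocorrelated or
heteroscedastic measurement error, curvature in the mineralization front,
partial sulfide re-oxidation or precipitation dynamics, compositional
artifacts of real amplicon libraries (chimeras, contamination, variable
copy number), or taxon dynamics within a phase. Real-data absolute MIN%
values additionally hinge on the true medium DIC concentration, which must
be supplied in the configuration.

## Problem sizes

Default test and simulation sizes are deliberately desk-scale: time
courses of 30–40 samples, Monte-Carlo recovery over 200 seeded replicates,
community tables of 20 taxa × up to 27 samples at 5 000–20 000 reads. These
sizes are sufficient for the asserted 3-SE statistical bands and keep the
full suite in the seconds range.

## Known limitations

* Phase windows snap to sample times; transitions between samples bias the
  phase-1 rate (never the phase-2 rate, which is slope-invariant within the
  linear segment) — sampling should bracket the expected corners.
* The hinge fit assumes a single monotone sulfide rise; exotic profiles
  (transient sulfide, double onsets) will be fit by their best single-rise
  approximation.
* The ANOVA is the standard fixed-effects design; unbalanced single-
  replicate groups contribute no within-group information.
* PCoA on strongly non-Euclidean Bray–Curtis matrices discards the
  negative-eigenvalue part of the variance (reported, not corrected).
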