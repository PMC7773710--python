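# acemin

Analysis pipeline for **¹³C-acetate mineralization microcosms**: sediment
incubations amended with uniformly ¹³C-labeled acetate that shift from a
brief oxic phase to sulfate-reducing conditions, monitored by δ¹³CO₂ and
dissolved sulfide over weeks to months at different incubation temperatures.
The package is aimed at biogeochemists and environmental microbiologists
running such tracer assays (e.g., in the context of aquifer thermal energy
storage and aquifer bioremediation) who need a reproducible route from raw
time courses and 16S ASV tables to per-phase rates, stoichiometric balances
and community-succession ordinations.

## What it computes

**Isotope mass balance.** The percent of amended acetate mineralized between
two δ¹³CO₂ readings (‰ vs VPDB) in a bicarbonate-buffered medium:

    MIN% = 100 · [HCO₃⁻] · R_VPDB · (δ_end − δ_start)/1000
           ─────────────────────────────────────────────────
           n · [acetate] · (1 + R_VPDB · (1 + δ_start/1000))

with `n` the number of labeled carbons (2 for uniformly labeled acetate).
An exact atom-fraction balance (including the growth of the DIC pool by the
mineralized carbon and the 99 atom % label purity) serves as an independent
oracle — the linearized formula tracks it to ~1 % across the assay range —
and its algebraic inverse drives the forward simulator.

**Biphasic kinetics.** Each replicate is segmented into an oxic phase 1
(δ¹³CO₂ rise to a plateau, no sulfide) and a sulfidogenic phase 2 (renewed
δ¹³CO₂ rise with sulfide production, located by a robust hinge fit to the
sulfide series). Phase rates are endpoint differences over window duration
(μM d⁻¹), summarized per temperature as mean ± sample SD.

**Stoichiometry.** Complete aerobic oxidation consumes 2 mol O₂ per mol
acetate (theoretical oxygen demand); complete oxidation by dissimilatory
sulfate reduction, CH₃COO⁻ + SO₄²⁻ → 2 HCO₃⁻ + HS⁻, yields 1 mol sulfide
per mol acetate. The sulfide:acetate molar ratio per temperature, its
Shapiro–Wilk normality check and a one-way ANOVA complete the balance.

**Community succession.** Relative abundances of ASV count tables, taxon
aggregation with an "Others" bucket (max-over-samples threshold rule, 5 %
at order rank / 3 % at genus rank), seeded rarefaction to a common depth,
Bray–Curtis dissimilarity, classical-scaling PCoA and a silhouette score
quantifying phase-cluster separation.

**Synthetic data.** A forward model (piecewise-linear biphasic
mineralization + Dirichlet-multinomial communities) generates complete
study bundles so every stage is testable without the deposited sequence
data, and parameter recovery can be asserted exactly.

## Worked example

```python
import numpy as np
from acemin import (MineralizationContext, preset_config, default_time_grid,
                    simulate_timecourse, analyze_timecourse)

ctx = MineralizationContext()          # 30 mM HCO3-, 1 mM acetate, n = 2
cfg = preset_config(25, noise=False)   # 25 degC study conditions
tc = simulate_timecourse(cfg, default_time_grid(cfg), "T25_r1")
for r in analyze_timecourse(tc, ctx):
    w = r.window
    print(f"phase {w.phase_label}: {w.t_start_d:.1f}-{w.t_end_d:.1f} d  "
          f"MIN% {r.min_pct:5.1f}  amount {r.amount_uM:6.1f} uM  "
          f"rate {r.rate_uM_per_d:5.1f} uM/d")
```

prints

```
phase 1: 0.0-2.4 d  MIN%  17.9  amount  179.3 uM  rate  75.0 uM/d
phase 2: 10.0-53.6 d  MIN%  82.1  amount  820.6 uM  rate  18.8 uM/d
```

i.e., the oxygen inventory (358.5 μM → 179.3 μM acetate at 2 O₂ : 1
acetate) caps the aerobic burst at 75 μM d⁻¹ within ~2.4 days; after a lag,
sulfate reduction mineralizes the remaining ~82 % at 18.8 μM d⁻¹, with
sulfide tracking the mineralized acetate at the configured molar yield.

The same works from the shell:

```bash
acemin simulate --out-dir data --seed 1
acemin report data/timecourses.csv --counts data/asv_counts.tsv \
    --taxonomy data/taxonomy.tsv --metadata data/sample_metadata.tsv \
    --out-dir report
```

which writes the per-replicate phase table, per-temperature summaries, the
sulfide/acetate balance, ratio statistics, aggregated abundances, the
Bray–Curtis matrix and PCoA coordinates. `examples/config.yaml` documents
every tunable constant.

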