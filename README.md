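# phasedyn

Phase-based static and dynamic functional connectivity for node-level
resting-state fMRI time series, with covariate-adjusted group inference.

## The problem

Across the Alzheimer's-disease continuum (subjective cognitive impairment
→ mild cognitive impairment → AD), whole-brain oscillatory coordination
is thought to degrade: the brain visits a narrower repertoire of
synchronization states. Session-averaged ("static") connectivity misses
this; time-resolved phase metrics capture it. `phasedyn` implements the
full analysis chain for panels of node time series (e.g. ICA component
time courses, 26 nodes × 202 volumes at TR = 2.638 s):

- **Narrowband phases** — linear detrend, zero-phase 4th-order
  Butterworth band-pass (0.04–0.07 Hz), analytic signal
  z(t) = x(t) + i·H[x(t)], envelope a(t) = |z(t)| and phase
  φ(t) = arg z(t), 10 points trimmed per end; tSNR quality control.
- **Static FC (sFC)** — L1-regularized inverse covariance (graphical
  lasso) on standardized series; partial correlations
  p_ij = −Ω_ij/√(Ω_ii Ω_jj), Fisher z = atanh(p), vectorized in the
  canonical 1-based row-major upper-triangle edge order
  ((1,2), (1,3), …, (n−1,n); 325 edges for 26 nodes).
- **Dynamic FC (dFC)** — Kuramoto order parameter
  R(t) = |N⁻¹ Σ_k e^{iφ_k(t)}|, **metastability** = SD of R(t);
  instantaneous pairwise coupling C_ij(t) = 1 − Δφ_ij(t)/π with
  Δφ the circular phase distance in [0, π]; per-edge dFC metric =
  coefficient of variation of C_ij(t) over time.
- **Surrogate tests for genuine dynamics** — multivariate
  phase-randomized Fourier surrogates (one common rotation across nodes
  per frequency, preserving every auto- and cross-correlation exactly),
  each surrogate pushed through the identical filter → phase → dFC
  pipeline; whole-brain (one-sample T vs surrogate T* over a grid of
  population means) and per-edge tests with
  p = 1 − #{T > T*}/n_surrogates.
- **Group inference** — per-edge pairwise logistic regressions and a
  multinomial logit of diagnosis on metastability, both adjusted for sex,
  age, head-coil and motion; the network-based statistic (NBS): edgewise
  ANCOVA F, primary threshold at p = 0.05, connected-component extent,
  family-wise error control by Freedman–Lane permutation of
  covariate-adjusted residuals; per-node summed-F contributions.
- **Synthetic cohorts** — noisy Kuramoto oscillators with natural
  frequencies in the analysis band and group-dependent global coupling
  (ground-truth metastability ordering), and stationary linear vector
  AR(1) null cohorts that carry no genuine dynamics, plus covariate
  tables with a realistic group age imbalance.

## Worked example

```python
import pandas as pd
from phasedyn import (SimulationConfig, generate_cohort, bandpass_filter,
                      analytic_phase, dynamics_cohort, DesignMatrix,
                      metastability_multinomial)

config = SimulationConfig()            # 3 groups x 26 subjects, 26 nodes
panels, cohort = generate_cohort(config, spec_seed=1)
phases = [analytic_phase(bandpass_filter(p, 0.04, 0.07), trim=10)
          for p in panels]
states, dfc, summary = dynamics_cohort(phases)

table = cohort.table.set_index("subject_id")
print(summary["metastability"].groupby(table["group"]).mean().round(4))

design = DesignMatrix.from_cohort(cohort, reference="SCI")
fit = metastability_multinomial(summary["metastability"].to_numpy(), design)
print(fit.summary.round(4))
```

Output:

```
group
AD     0.0903
MCI    0.1266
SCI    0.1516
Name: metastability, dtype: float64
           coef       se       p
group
AD    -204.8086  44.8131  0.0000
MCI    -67.1101  20.1294  0.0009
```

Group-mean metastability falls monotonically from SCI to AD — the
healthier the group, the closer its coupling sits to the critical point
where synchrony fluctuates most. The multinomial logit (SCI as
reference, adjusted for sex, age, head-coil and motion) assigns both
impaired groups negative, significant metastability coefficients; the
coefficients are large because metastability lives on a ~0.1 scale.

A command-line interface mirrors the library:
`phasedyn simulate|phase|sfc|dfc|surrogate|infer|run` (see
`phasedyn --help`), and `phasedyn run --config run.toml` executes the
whole pipeline with per-stage artifacts and a reproducibility manifest.

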