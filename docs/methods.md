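# Methods

## Signal model and phase extraction

The pipeline treats each subject's data as an M-node panel x_k(t),
k = 1..M, sampled every TR seconds (defaults: M = 26, 202 samples,
TR = 2.638 s). Instantaneous phases are only meaningful for narrowband
signals, so each node series is linearly detrended and band-passed to
0.04–0.07 Hz with a 4th-order Butterworth filter applied
forward–backward (zero-phase, so phase relationships between nodes are
untouched). The filter is padded with the full series length: the
narrow band has an impulse response comparable to the record length, and
short padding both distorts the ends and breaks the exact
time-reversal symmetry that the zero-phase contract promises. Any
numerically residual DC is removed exactly after filtering.

The analytic signal z(t) = x(t) + i·H[x(t)] is computed by FFT over the
whole series; envelope a(t) = |z(t)| and phase φ(t) = arg z(t) wrapped to
(−π, π]. Ten points are dropped from each end (configurable) to
suppress transform border effects, leaving 182 usable samples of the
202. tSNR (temporal mean / temporal SD per node, averaged over nodes) is
provided for quality control; zero-variance nodes are excluded with a
warning rather than silently producing infinities.

## Connectivity metrics

**Static (sFC).** On standardized series, the precision matrix Ω is
estimated by L1-penalized Gaussian likelihood (graphical lasso;
`scikit-learn`), and converted to partial correlations
p_ij = −Ω_ij/√(Ω_ii·Ω_jj), then Fisher z-transformed. The penalty λ
defaults to 0.1 on standardized data — a conventional mild value; no
reference value is available for the original analysis, so λ is an
explicit parameter and the test suite checks behaviour across a grid
(sparsity is monotone in λ; λ = 0 reproduces the closed-form inverse).
λ = 0 falls back to direct inversion of the sample covariance. sFC is
computed on the unfiltered (full-band) series; the 0.04–0.07 Hz band is a
requirement of the phase metrics only. Edges are stored in the canonical
1-based row-major upper-triangle order ((1,2), (1,3), …, (n−1,n)); for
26 nodes, pair (2,13) is edge 36, (7,8) is 136, (11,20) is 214.

**Dynamic (dFC).** From the trimmed phases: the Kuramoto order parameter
R(t) = |N⁻¹ Σ_k e^{iφ_k(t)}| per time point, and metastability = sample
SD of R(t) (ddof = 1 by default; exposed as a flag along with the CV
numerator). Pairwise coupling uses the circular phase distance
Δφ_ij(t) = min(|φ_i − φ_j| mod 2π, 2π − |φ_i − φ_j| mod 2π) ∈ [0, π],
normalized as C_ij(t) = 1 − Δφ_ij(t)/π ∈ [0, 1]; the wrap rule is the
unique choice that keeps C in [0,1]. The per-edge dFC metric is the
coefficient of variation of C_ij(t) over time; an edge whose temporal
mean C falls below 1e−6 has an undefined CV and is reported as NaN,
never as zero. The vectorized implementation computes the two temporal
moments of C per edge row (slice-based, no gather) and is verified
against the direct per-subject construction to machine precision.

## Surrogate tests for genuine dynamics

Null hypothesis: the observed dFC values are what any stationary linear
process with the same auto- and cross-correlations would produce.
Surrogates rotate the Fourier phases of the *unfiltered* series with one
random phase sequence shared by all nodes per frequency (DC and Nyquist
untouched, conjugate symmetry enforced). The common rotation leaves every
amplitude spectrum and every cross-spectrum exactly invariant, so
auto- and lagged cross-correlations are preserved to machine precision —
only phase relationships *across frequencies* (the genuine temporal
dynamics) are destroyed. Each surrogate then passes through the same
filter → analytic phase → trim → dFC code path as the measured data, by
construction (one function implements that path).

Two tests compare measured one-sample T statistics against their
surrogate counterparts T*, with p = 1 − #{T > T*}/S (strict inequality,
as printed; a +1 small-sample correction is available behind a flag and
off by default):

- *whole-brain*: per-subject sums of all unique dFC values, tested
  against a grid of population means from 0 to the maximum surrogate sum,
  giving a detection-probability curve;
- *per-edge*: the reference (healthiest) group's dFC values per edge
  tested against mean 0; the test's discriminative content is entirely in
  the T vs T* comparison — since CVs are positive, both T and T* are
  large by construction, and this is implemented literally.

Achievable p-values lie on the grid {0, 1/S, …, 1}. The desk default is
S = 1000 (the original design used 10000; available via configuration).

## Group inference

All models adjust for sex, age, a head-coil dummy (1 = 8-channel) and
mean relative motion.

- **Edgewise pairwise logistic regressions**: diagnosis pair as outcome,
  one edge metric at a time plus covariates. Coefficients and SEs are
  Wald; the per-edge p comes from the likelihood-ratio test of the edge
  term against the covariates-only fit, because with strong edge effects
  the Wald statistic collapses (Hauck–Donner) and perfectly separated
  fits abort. A separated edge keeps its `separation` flag and NaN
  coefficient but receives the LR supremum p = χ²₁-sf(−2·llf_null).
  P-values are deliberately unadjusted at this stage (a Bonferroni column
  is reported alongside).
- **Multinomial logit** of diagnosis on metastability plus covariates,
  configurable reference category; reports per-contrast Wald tests,
  McFadden pseudo-R² and the log-likelihood (`statsmodels` MNLogit).
  Two-class designs are accepted (the fit then equals binary logistic,
  which the tests verify); single-class designs are rejected.
- **NBS**: per edge, the ANCOVA F for the group factor given covariates;
  edges with F above the parametric quantile at the primary p (0.05
  default) form a graph whose connected components are scored by extent
  (edge count — the standard choice; the reported subnetworks are sized
  in edges). The null distribution of the maximum component extent is
  built by Freedman–Lane permutation: residuals of the covariates-only
  fit are permuted and added back to the covariate fit, so nuisance
  structure is respected without assuming the group labels are
  exchangeable given covariates. Component FWE p uses
  (1 + #{null ≥ observed})/(1 + n_perm), which cannot return 0.
  A tiny-instance exhaustive mode (intercept-only nuisance model)
  enumerates all distinct label assignments and is verified against an
  independent brute-force oracle. Per-node contributions sum F over
  significant-component edges incident to each node, optionally averaged
  over the sFC and dFC runs.

## Synthetic cohorts (what they emulate, and what they do not)

**Oscillator cohorts.** Each subject is a Kuramoto system
dθ_k/dt = ω_k + Σ_j K_kj sin(θ_j − θ_k) + phase noise, integrated by
Euler–Maruyama at dt = TR/20 (>100 steps per 0.07 Hz cycle; steps
coarser than TR/10 are rejected), with ω_k/2π uniform on 0.04–0.07 Hz,
a 120 s burn-in, observation x_k = sin θ_k sampled every TR plus
Gaussian measurement noise (SD 0.1), and phase noise 0.15 rad/√s.
Group structure enters through the global coupling K (all-to-all K/N
weights, per-subject jitter SD = 10% of K). Metastability as a function
of K is non-monotone: it rises from the incoherent finite-size
fluctuation level (~0.09 at K = 0 under these settings), peaks near the
critical coupling (~0.16 at K ≈ 0.09), and collapses toward 0 in the
synchronized regime — the classic critical-coupling picture. The group
defaults K = 0.08 (SCI), 0.05 (MCI), 0.02 (AD) sit on the rising branch,
chosen once by a coarse sweep so that 26 subjects per group give >80%
power in the multinomial logit and a strictly ordered group mean in ≥90%
of cohorts (both verified by simulation in the test suite). Covariates:
age normal with group means 71.5/63.5/63.6 (SD 7.9/11.1/9.6) years,
balanced sex, 73% 8-channel head coil, log-normal motion (median
0.1 mm) — enough structure to exercise confound adjustment.

**Stationary null cohorts.** A linear Gaussian vector AR(1) process
x_t = a·x_{t−1} + ε_t with innovations scaled so the stationary
cross-covariance equals the requested matrix exactly. Its distribution is
invariant (up to the randomized phases) under the surrogate
construction, so it is the calibration null for the dynamics tests, the
NBS and the edgewise regressions.

Neither generator models hemodynamics, anatomical connectivity or
spatially structured noise; passing tests demonstrate the statistical
machinery's correctness and calibration, not fidelity to any particular
empirical dataset.

### A note on the direction of the dFC summary

Coupling *suppresses* the dFC coefficient of variation: at supercritical
K the phases lock, C_ij(t) concentrates near 1 and its relative
variability collapses (cohort dFC sums ≈ 10–20 versus ≈ 185 for a
matched stationary null at these dimensions). The raw dFC sum therefore
separates the generators in the *lower-than-null* direction, and the
one-sided whole-brain surrogate test — which looks for dFC *larger* than
surrogates — has little power against subcritical oscillator cohorts.
This mirrors the empirical situation: detecting weak dFC at these sample
sizes is hard, which is exactly why the surrogate tests are part of the
pipeline rather than an afterthought.

Similarly, sFC (Fisher-z partial correlations) and dFC (CVs) share
sampling variation with opposite signs — a subject/edge whose realized
correlation is high has a higher mean C and hence a *lower* CV — so even
on stationary null data the two metrics show a mild negative association
(median Pearson r ≈ −0.2 to −0.3 at these dimensions). The property
tests assert weak association at the level that holds
(median r ∈ (−0.45, 0.05)) rather than near-zero correlation.

## Numerical choices and problem sizes

- SD convention: sample (ddof = 1) throughout, exposed as a parameter.
- Order of operations: filter → Hilbert → trim → all phase metrics.
- p-counting: strict inequality for surrogate tests; +1/(n+1) for NBS.
- Edge p-values: LR test (see above); Wald SEs reported.
- The calibration and recovery test suites run at reduced sizes chosen as
  the package's own desk defaults: 1000 surrogates and 500 permutations,
  12-node/10-subject cohorts for the 20-replicate whole-brain and NBS
  calibrations, the full 26-node/26-subject design for the per-edge
  uniformity check and the 20-replicate parameter-recovery study.
  `scripts/acceptance.py` uses 200 surrogates and 1000 permutations for
  its single full-pipeline run.

## Known limitations

- The graphical-lasso penalty for the original analysis is unknown;
  sensitivity is documented via the λ-grid property tests rather than
  resolved.
- Whether the original pipeline detrended again before the narrowband
  filter is unreported upstream; this implementation detrends (the
  pass-band makes results insensitive to slow drifts).
- Whether metastability was computed on the same trimmed narrowband
  phases as the pairwise metrics is assumed (one phase pipeline).
- The per-edge surrogate test against a population mean of zero is kept
  literally as designed; its p-values are informative only relative to
  the surrogate distribution, not as absolute tail probabilities.
- Real resting-state data have hemodynamic smoothing, spatially
  correlated noise and motion artifacts that the generators do not
  emulate; calibration results transfer only to the extent that the
  stationary-linear null is adequate.
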