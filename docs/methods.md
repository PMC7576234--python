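# Methods

## Scope

`nadscope` implements two computational procedures for studying cardiac
energetics and NAD metabolism, joined by a study-shaped orchestration
layer and driven end to end by synthetic-data generators with known
ground truth:

1. **Dynamic ³¹P-MRS quantification** — preprocessing (phasing, PCr
   alignment, baseline removal) and constrained Lorentzian-multiplet
   deconvolution of in vivo cardiac phosphorus spectra, yielding the
   PCr/γ-ATP ratio and α-ATP-normalized levels of NAD⁺, cytosolic
   NADH/NADP⁺/NADPH, UDP-glucose and mitochondrial NAD(P)H.
2. **MNAR-aware metabolomics statistics** — log₂ transform, cyclic LOESS
   normalization, a >40% missingness filter, QRILC imputation of
   left-censored values, metabolite-wise linear models with
   empirical-Bayes variance moderation, Benjamini–Hochberg FDR control
   at 10%, and untransformed fold changes with delta-method standard
   errors.

## The spectral model

A spectrum is modeled as a sum of Lorentzian multiplets over a smooth
baseline.  A unit-area Lorentzian is

    L(x; c, w) = (w/π) / ((x − c)² + w²),

with `c` the chemical shift (ppm) and `w` the half-width at half-maximum
(HWHM, ppm); apex amplitude and area are related by `area = π · apex · w`.
Each resonance is a rigid multiplet: components at fixed spacings
(`coupling_ppm`) with fixed relative amplitudes (`component_ratios`),
sharing a single area parameter.  Hard prior-knowledge constraints:

- **Shared line width.** All cytosolic/shared-class peaks (α-ATP, NAD⁺,
  NADH, NADP⁺, NADPH, UDP-glucose) use one common HWHM per fit.  This is
  a hard equality constraint (one parameter), not a penalty.
- **Mitochondrial NAD(P)H width.** Parameterized as `shared_width ×
  ratio` with the ratio box-bounded to [1.5, 3.0], reflecting the
  broader line of the matrix-localized pool.  A fit whose ratio pins at
  a bound is flagged `boundary_active`.
- **Center jitter.** Peak centers may drift at most ±0.05 ppm (default)
  from their library positions, accommodating small in vivo shifts
  while keeping assignments fixed.
- **Non-negativity.** Areas are bounded below by zero.

Estimation is bounded trust-region least squares
(`scipy.optimize.least_squares`, `trf`, ftol 1e-10, xtol 1e-8) from a
deterministic initial guess (amplitudes read off the spectrum at the
nominal centers; HWHM 0.08 ppm) plus two seeded, jittered restarts; the
best of the three fits is kept, so the procedure is deterministic given
the seed.  Areas are the fitted parameters themselves — no numeric
integration of the fitted curve is involved.

Relative quantification divides every non-ATP area by the α-ATP area
(α-ATP maps to exactly 1).  The PCr/ATP ratio is computed independently
of the model by trapezoidal window integration (defaults: PCr in
[−3.5, −1.5] ppm, γ-ATP in [−6, −4] ppm), the classical integral-based
path; model-based areas are also available.

### Peak library

The default library (PCr singlet anchored at −2.54 ppm, γ-/α-ATP 1:1
doublets with 0.21 ppm P–P splitting, the NAD(P)(H)/UDP-glucose cluster
downfield of α-ATP, a broad mitochondrial NAD(P)H singlet) uses
literature-typical ³¹P positions on the PCr = −2.54 ppm referencing
convention.  The library is configuration (YAML), not code: every
correctness test generates its ground truth from the same library it
fits with, so the shipped default positions never gate correctness.

### Preprocessing

- **Phasing.** `S·exp(i(φ₀ + φ₁(δ − δ_pivot)))`, real part returned.
  Auto mode minimizes the summed squared negative excursion of the real
  channel, evaluated on a lightly smoothed (9-point) spectrum; by
  default only φ₀ is searched (coarse grid + bounded 1-D refinement)
  because φ₀ and φ₁ are nearly degenerate when peaks occupy a narrow
  ppm range.  On noiseless synthetic spectra the recovery error is
  <0.01 rad; under noise the negativity criterion acquires a bias of
  order 0.05–0.1 rad at SNR 20 — a known limitation of the criterion,
  which is why simulated cohorts default to zero injected phase error.
- **PCr alignment.** The apex of the tallest point in the search window
  (default [−6, 2] ppm) is refined by parabolic interpolation through
  its three neighbors and shifted to −2.54 ppm; recovery is accurate to
  well below one grid step.
- **Baseline.** Two stages: an asymmetric-least-squares Whittaker
  smoother (asymmetry p = 1e-3, smoothness λ = 1e7, second-difference
  penalty) to obtain a robust, peak-insensitive first estimate, then an
  iterated re-smoothing in which points more than 3 robust SDs above
  the current baseline are masked entirely and the rest weighted
  symmetrically.  The second stage removes the low-quantile bias that
  plain asymmetric weighting imposes in noise (the asymmetric stage
  alone settles near the −2.3σ noise quantile at p = 1e-3).  A caveat
  inherent to Lorentzian spectra: 1/x² tails overlap everywhere, so the
  estimated "baseline" of a peaks-only spectrum converges to the tail
  floor (≲1% of the tallest apex for the default cardiac spectrum),
  not to machine zero.  An iteratively clipped polynomial fallback
  (`method="poly"`) is provided.

## The metabolomics chain

- **log₂ transform** of present cells only; empty cells, `NA` and (by
  MS convention, configurable) literal zeros are treated as missing.
- **Cyclic LOESS.** For every ordered sample pair, M = xᵢ − xⱼ is
  smoothed against A = (xᵢ + xⱼ)/2 (local-linear LOESS, span 0.7) over
  cells present in both samples, and half the fitted trend is moved
  from one sample to the other; the sweep repeats for 3 cycles.  Each
  pair adjustment preserves the pair's grand mean exactly, and missing
  cells are untouched.  Span and cycle count are configuration; the
  defaults follow common benchmark usage.
- **Missingness filter.** Metabolites missing in strictly more than 40%
  of samples are excluded; exactly-40% rows are retained.  Idempotent.
- **QRILC imputation**, per sample.  With missing fraction m, the
  observed values are the upper (1 − m) tail of the uncensored
  distribution; sorted observed value k sits at overall quantile
  p_k = m + (1 − m)(k − ½)/n.  Under the Gaussian model the sorted
  values are linear in Φ⁻¹(p_k), so ordinary least squares on this grid
  recovers (μ, σ) — the same estimand as the quantile-regression
  formulation, chosen for simplicity and testability (a check-loss fit
  would add nothing under the Gaussian model).  Each missing cell is
  drawn from N(μ, σ²) truncated above at μ + σΦ⁻¹(m), so every imputed
  value lies in the censored lower tail.  Observed cells are never
  altered; draws are deterministic given the seed.  No variance
  inflation factor is applied to σ (factor 1).  Samples with ≥50%
  missing or <5 observed values are rejected.
- **Moderated linear models.**  Per metabolite, OLS of log₂ intensity
  on an intercept, treatment-coded group (reference: old control),
  preparation-batch dummies and z-scored protein concentration (a
  constant covariate is dropped; rank-deficient designs are rejected
  with the aliased columns named).  Residual variances are shrunk via
  the scaled inverse-chi-square prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ +
  d_g), with (d₀, s₀²) estimated by matching the first two moments of
  log s²_g to the log scaled-F distribution (digamma/trigamma
  inversion, Newton).  The moderated t = β̂/(s̃_g√v_g) has d₀ + d_g
  degrees of freedom.  When the observed spread of log-variances does
  not exceed chi-square sampling noise the trigamma inversion has no
  finite solution; the model then reports unmoderated statistics with a
  warning.
- **BH FDR** per contrast (step-up adjusted p-values via statsmodels),
  flagging q < 0.10; joint adjustment across contrasts is available
  behind a flag.
- **Fold changes.** fc = 2^β̂ with delta-method SE, se_fc = ln 2 · 2^β̂ ·
  se_β (using the moderated se_β), rows ordered by fold change
  descending.  The delta method was chosen over an endpoint transform
  for the SE back-transform; a Monte-Carlo check at β̂ = 1, se = 0.1
  agrees within 2%.

## Study orchestration

The paired design is handled at the animal level: per-animal deltas
(post − pre) of PCr/ATP and the fitted relative levels, per-group
one-sample t tests of the mean delta against zero, and fixed-effects
ANOVA (one-way across groups; two-way group × state available).  SEMs
are computed on per-animal deltas, respecting the pairing.  The
cross-method table normalizes MRS and metabolomics level vectors each
to its own mean NAD⁺ before comparison, and excludes mitochondrial
NAD(P)H, which an extraction-based method cannot separate from the
cytosolic pools.  All randomness in `run_study` flows from one master
seed expanded into per-stage seeds recorded in the run log; rerunning
with the same seed reproduces every output file byte for byte.

## Synthetic data: what it emulates, and what it does not

**Spectra** are complex-valued sums of multiplet Lorentzians (matching
absorptive/dispersive pairs) plus a polynomial baseline, rotated by an
injected zero/first-order phase error, with i.i.d. Gaussian noise on
both channels.  SNR is defined as tallest noiseless apex over
per-channel noise SD; the default study condition is SNR 20.  Default
truth areas give a resting PCr/ATP of 1.8 and minor-metabolite levels
of the order seen in vivo.  Censoring, line-shape distortions from
shimming, eddy currents, residual water/overlapping phospholipid
signals, and acquisition physics (localization, gating, averaging) are
*not* simulated — recovery results certify the estimator under its own
model plus noise, not robustness to lineshape misspecification.

**Cohorts** pair a pre and post spectrum per animal.  Each animal
carries a log-normal biological effect per peak (SD 10%, shared between
states) and each acquisition a log-normal occasion effect per peak (SD
5%); post-state areas are additionally scaled by the group's effect
profile (old-control default: PCr × 0.8).  The source study reports no
between-animal variance components, so these SDs are plausibility
choices, fixed once: 10% between-animal biological scatter is typical
of in vivo metabolite ratios, and the occasion term is what makes the
within-animal delta noisy (a purely shared animal factor would cancel
in every ratio).  The demo effect sizes are a calibration that
reproduces the qualitative study pattern by construction (old control
depleted, young flat, treated intermediate) — not a biological claim.

**Metabolite matrices** are log-normal: log₂ intensity = metabolite
mean (N(20, 2²)) + group effect + batch effect (N(0, 0.3²), 3 batches)
+ 0.2 × protein z-score + N(0, 0.5²) noise.  A third of a 1-log₂-unit
group effect magnitude matches the fold-change range (≈0.3–3×) of the
study's significant metabolites.  Left-censoring is a hard threshold at
the LOD — chosen because QRILC's model is a truncated distribution —
with the LOD placed at the 1st percentile of the marginal distribution
so post-filter missingness lands near 1%, the scale reported for the
real data; a logistic soft censor is available but off by default.
Real MS features not emulated: correlated metabolites, heteroscedastic
(intensity-dependent) noise, MCAR/MAR admixture, batch-by-metabolite
interactions.

## Problem sizes used by the test suite and acceptance script

Fits use ~2,800-point axes (0.005 ppm grid over −13.5 to 1.5 ppm); the
Monte-Carlo recovery study uses 100 seeds at SNR 20; the cohort power
calibration uses 50 replicate cohorts of 11 animals/group (young and
old-control arms, the two the calibration claim concerns), with
PCr/ATP computed by window integration; the null calibration of the
moderated t uses 200 replicates of 500 metabolites at n = 10 vs 10.
These sizes give sampling error comfortably below each check's margin.

## Known limitations

- The negativity-based auto-phaser is biased under noise (see above);
  spectra should be phased at high SNR or with the manual path.
- The baseline estimate cannot distinguish overlapping Lorentzian tail
  floor from true baseline; areas from the model fit (which include the
  tails) are unaffected, but window integrals on baseline-corrected
  spectra lose the tail fraction.
- QRILC's per-sample Gaussian assumption is wrong for strongly skewed
  sample distributions; with the study-scale missingness (~1%) the
  imputation's influence on downstream statistics is small.
- The moderated model assumes a common variance prior across
  metabolites; heavy-tailed variance distributions inflate d₀ slightly
  (moment matching, not ML).
- Peak-library default positions are representative, not calibrated
  against chemical standards; real-data use requires a library measured
  on the instrument at hand.
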