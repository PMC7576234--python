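# nadscope

Quantification of dynamic cardiac energetics from in vivo ³¹P magnetic
resonance spectra, and an MNAR-aware statistics chain for targeted
metabolomics matrices — built for studies that probe how the aging heart's
metabolite pools (PCr, ATP, NAD⁺/NADH, NADP⁺/NADPH, UDP-glucose) respond
to an acute workload challenge.

## Who this is for

Groups running paired rest/stress ³¹P-MRS in small animals who need
automated, constraint-based spectral deconvolution instead of manual peak
integration, and groups analyzing targeted LC-MS metabolite matrices whose
missing values are left-censored (below the limit of quantification,
missing-not-at-random).

## What it computes

**MRS arm.** After phasing, alignment of PCr to −2.54 ppm and baseline
removal, spectra are fit with a sum of Lorentzian multiplets under hard
prior-knowledge constraints: fixed multiplet geometry per resonance, one
shared half-width for all cytosolic peaks, a mitochondrial NAD(P)H width
bounded to 1.5–3× the shared width, and centers allowed only ±0.05 ppm of
jitter.  For a Lorentzian with apex amplitude A and half-width w the area
is π·A·w, computed analytically from the fitted parameters.  Readouts are
PCr/γ-ATP (by trapezoidal window integration) and each minor metabolite's
area normalized to α-ATP.  The paired design yields per-animal deltas
Δ = post − pre, tested per group with one-sample t tests and across groups
with ANOVA.

**Metabolomics arm.** log₂ → cyclic LOESS normalization (pairwise M-vs-A
local regression) → exclusion of metabolites >40% missing → QRILC
imputation (per-sample truncated-normal draws with (μ, σ) estimated by
regressing observed order statistics on normal quantiles) → per-metabolite
linear models with group, preparation-batch and protein-concentration
covariates → empirical-Bayes variance moderation
(s̃² = (d₀s₀² + d·s²)/(d₀ + d), moderated t with d₀ + d df) →
Benjamini–Hochberg FDR at 10% → untransformed fold changes 2^β̂ with
delta-method standard errors.

Synthetic-data generators (`nadscope.simulate`) produce spectra, paired
cohorts and left-censored metabolite matrices with known ground truth, so
the whole pipeline is testable with no external data.  See
`docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from nadscope import (LorentzianMultipletModel, default_spectrum_truth,
                      simulate_spectrum)
from nadscope.peaks import nad_region_library

lib = nad_region_library()                       # the 7-peak NAD-region model
truth = default_spectrum_truth(snr=20.0, names=lib.names, seed=7)
spectrum, truth = simulate_spectrum(truth)

fit = LorentzianMultipletModel(spectrum, lib).fit(seed=7)
print(fit.summary())
```

```
Constrained Lorentzian multiplet fit
======================================================
peak           center    HWHM        area  rel(aATP)
------------------------------------------------------
alphaATP      -10.053   0.080      1.6056     1.0000
NADPplus      -10.505   0.080     0.24756     0.1542
NADplus       -10.779   0.080     0.43051     0.2681
NADH_cyt      -11.078   0.080     0.13478     0.0839
mitoNADPH     -11.341   0.172     0.25554     0.1592
NADPH_cyt     -11.602   0.080     0.18888     0.1176
UDPglucose    -11.922   0.080     0.20226     0.1260
------------------------------------------------------
shared HWHM = 0.0796 ppm   mito ratio = 2.156
residual SSE = 13.84   converged = True   starts = 3
```

The ground truth behind this spectrum has α-ATP area 1.6, NAD⁺ 0.45 and
mitochondrial NAD(P)H 0.25 at twice the shared width: at SNR 20 every
shared-width area is recovered within a few percent, and the broad,
low-amplitude mitochondrial peak — the hardest parameter — within ~2%
here (its median error across seeds is ~15%).  `rel(aATP)` is the
relative quantification used for group comparisons.

The full synthetic study (cohort simulation → preprocessing → fits →
paired deltas → group tests → metabolomics chain → cross-method table)
runs from the command line:

```bash
nadscope study run --seed 1 --out study_out
```

```
Delta PCr/ATP OldCombined  mean -0.128 +/- 0.068 (n=11), p_vs_0 = 0.0886
Delta PCr/ATP OldControl   mean -0.292 +/- 0.057 (n=11), p_vs_0 = 0.0004
Delta PCr/ATP OldNMN       mean -0.110 +/- 0.044 (n=11), p_vs_0 = 0.0323
Delta PCr/ATP OldSS31      mean -0.132 +/- 0.077 (n=11), p_vs_0 = 0.1157
Delta PCr/ATP Young        mean +0.085 +/- 0.049 (n=11), p_vs_0 = 0.1107
Metabolomics: 200 metabolites post-filter; 44 significant (metabolite, contrast) pairs at q < 0.1
```

The simulated old-control hearts deplete PCr under workload (mean
Δ(PCr/ATP) ≈ −0.3, p < 0.001) while the young group stays flat — the
qualitative pattern the demo cohort is calibrated to produce.  Other CLI
entry points: `nadscope simulate spectra|metabolome`, `nadscope mrs fit`,
`nadscope metabo run` (see `--help`).

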