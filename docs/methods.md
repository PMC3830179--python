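# Methods

This note documents the models implemented in `nirqc`, the synthetic-data
generator that stands in for measured spectra, and the numerical and design
choices made where the method description leaves latitude.

## Formulation and blend designs

The capsule fill is AZ dihydrate 419 mg, AS 300 mg, microcrystalline cellulose
100 mg and colloidal silica 1.638 mg per unit (total 820.638 mg), giving label
mass fractions w_AZ = 0.5106 and w_AS = 0.3656. A blend design at level L (% of
label) for a varied API uses nominal masses

- varied API: (L/100) · w_varied · M_total
- fixed API: w_fixed · M_total
- placebo (cellulose + silica 40.7:1): M_total − both APIs (*quantum satis*),

with M_total = 2053.64 mg (calibration) or 1026.82 mg (validation). Masses are
reported to 0.01 mg and percentages to 0.01%. Published reference weighings for
these designs are actual balance readings; the test suite compares nominal API
masses to them at 0.5% relative and the small qsp placebo cells at 0.5% of the
blend mass, because the placebo cell absorbs the weighing error of two API cells
an order of magnitude larger. One recorded validation row whose total is 1.3%
above nominal is treated as a mis-weighing and excluded from that comparison.

## Synthetic spectra generator

The generator emulates the statistical structure the chemometrics assumes, not
radiative transfer:

- **Grid:** 4000–9999 cm⁻¹ digitized at 4 cm⁻¹ (1500 points). The instrument
  resolution is 8 cm⁻¹; 4 cm⁻¹ is a typical digitization interval for such data.
- **Pure spectra:** sums of Gaussian bands (center, SD width, height). Gaussian
  shapes (rather than Lorentzian/Voigt) admit closed-form unit tests. The band
  library is an invented stand-in for the real pure-compound spectra, built so
  that (a) each API has bands inside both analysis windows, (b) AZ dominates the
  blend spectrum at label composition, and (c) the degradant DHA equals the AS
  band set shifted by +30 cm⁻¹ with heights × 0.9 — close enough that detecting
  a 10%-degraded blend is non-trivial.
- **Mixing and noise:** a blend spectrum is g·Σᵢ fᵢ Aᵢ(ν) + b₀ + b₁·ν̃ + ε with
  mass fractions fᵢ, log-normal gain g (multiplicative scatter), a linear
  baseline in the normalized wavenumber ν̃, and iid Gaussian point noise — the
  effects SNV and derivatives are designed to remove. Defaults: gain SD 0.5%,
  offset and slope SD 5·10⁻⁴ AU, additive SD 10⁻⁴ AU, weighing SD 0.15%
  relative per component. These magnitudes represent a well-behaved FT-NIR
  diffuse-reflectance setup with carefully standardized powder presentation.
- **Repacks:** each sample spectrum is the mean of 3 independent recordings of
  the same weighed blend (vial turnover), so recording noise scales as σ²/3.
- **Series effects:** the intermediate-precision study applies one extra
  log-normal gain per series (log-SD 0.3%) to emulate day/operator changes.
- **Reproducibility:** one seed enters a `SeedSequence`; per-stage and
  per-sample substreams are spawned deterministically, so a run is
  bit-reproducible from (config, seed).

The generator's reference contents are gravimetric: the "true" percent of label
is computed from the perturbed (weighed) masses, exactly as an analyst would
know them. What it does **not** model: particle-size-dependent penetration
depth, instrument line shape, wavelength-correlated noise, band nonlinearity at
high absorbance, or drift within a series. Passing tests therefore demonstrate
the statistical machinery of the method under its own assumptions — not
instrument-transferable performance on real capsules.

## Preprocessing

Region 1 (5311–6811 cm⁻¹) is treated SNV-then-derivative; the wording of the
method description admits either order, and SNV-then-derivative is the
conventional reading (the order is configurable). SNV uses the sample SD
(n−1). The Savitzky–Golay derivative (window 11, polynomial order 2, first
derivative) is reported per cm⁻¹ (coefficients divided by the grid spacing), so
results are invariant to the digitization interval; the (window−1)/2 = 5 edge
points of each region are dropped rather than extrapolated, keeping the
convolution coefficients exact. Region 2 (7200–9999 cm⁻¹) enters raw. Region
bounds are closed intervals on the digitized grid (region 1 retains 375 points,
365 after edge trimming; region 2 retains 700). No block scaling is applied
between the two differently-treated regions (none is described; an autoscaling
flag could be added but the PLS results do not require it). Mean-centering is
applied after concatenation, with column means learned on the calibration set
and reused verbatim for any test set — test data never influence centering.

## PLS1

NIPALS with a single response: for each factor the weight vector is
w = X'y/‖X'y‖ (the fixed point of the inner iteration, so it converges in one
pass), scores t = Xw, loadings p = X't/t't, q = y't/t't, and X is deflated by
t p'. The regression vector b = W(P'W)⁻¹q. One model per API; no PLS2. Factor
count is selected by venetian-blinds cross-validation with 6 interleaved folds
stratified by concentration level (every fold spans all nine levels); the
selected count is the global RMSECV minimum with ties broken toward fewer
factors. Leave-one-out is available. External-set RMSEP is computed and labeled
separately from internal RMSECV. RMSEC/RMSEP/RMSECV are in % of label claim.

With all noise switched off, the calibration set varies along a single
composition direction, but the SNV normalization bends that direction into a
low-rank curve in feature space; three factors (one per independent blend
component) reproduce the true content to machine precision, and the test suite
asserts recovery below 10⁻⁸ % of label.

## PCA specificity library

PCA is computed by SVD of the centered feature matrix with a deterministic sign
convention (largest-magnitude loading element positive). A test sample is
accepted iff

- its Mahalanobis distance in score space (against the training score
  covariance, regularized by 1e−10·trace when near-singular) is below the
  square root of the χ²(k) 99.9% quantile, and
- its orthogonal residual norm is below mean + 5·SD of the training residuals.

The library retains **five** components by default: the two-API calibration set
spans two composition directions, and three instrumental directions survive
preprocessing in the raw block (multiplicative gain, baseline offset, baseline
slope). Retaining all five puts routine instrumental variation inside the model,
so the Q-style residual responds to new chemistry; with only two components the
residual floor is set by baseline noise and a 3.65% w/w degradant can hide
below it. The first two components still carry ~99.7% of the variance and the
familiar PC1/PC2 scores plot separates every challenge from the genuine cloud.
Measured over 20 independent seeds: 100% rejection of placebo, 10%-DHA and
pure-API challenges (also at a reduced DHA shift of 20 cm⁻¹) and ≥98%
acceptance of genuine validation spectra.

## Accuracy profiles

Relative recovery errors e = 100(recovered − level)/level are decomposed per
level by balanced one-way random-effects ANOVA (method of moments):
s_W² = MS_within, s_B² = max(0, (MS_between − MS_within)/n) — negative
between-series estimates are truncated at zero, the standard convention.
Unbalanced designs are rejected with an explicit error; the study design is
balanced (p = 3 series × n = 3 replicates per level, the assumed reading of
"three replicates on three days by two persons"; both counts are configurable).

The β-expectation tolerance interval is the Mee-type form with Satterthwaite
degrees of freedom (several variants exist in the accuracy-profile literature;
this one is implemented and verified by simulation):

R = s_B²/s_W², B² = (R+1)/(nR+1),
ν = (R+1)² / [(R+1/n)²/(p−1) + (1−1/n)/(p·n)],
limits = bias ± t_{ν,(1+β)/2} · s_IP · √(1 + 1/(p·n·B²)).

Degenerate cases: both variances zero → the point interval (bias, bias);
s_W² = 0 with s_B² > 0 (R → ∞) → B² = 1/n, ν = p−1. β defaults to 0.95 (the
customary choice where none is stated) and the acceptance limit λ to 5%, the
stated criterion for this formulation. Monte-Carlo checks confirm the
β-expectation property (average coverage of future observations ≈ β within
sampling error) and that limits widen monotonically in β and s_B².

## Problem sizes and run times

The default study uses the full designs (54 calibration / 27 validation
samples per API, 27-sample validation studies, 12 challenge spectra) and runs
in about two seconds; the complete test suite, including the 20-seed
specificity property and ~10⁵-draw coverage simulations, runs in well under a
minute. Monte-Carlo sample counts in the tests were sized for stable assertion
margins at those tolerances.

## Known limitations

- The band library is synthetic; figures of merit (RMSEC ≈ 0.01% of label) are
  far better than any real NIR assay because the simulated noise is mild and
  perfectly matches the model class. Threshold-style conclusions (r ≥ 0.999,
  profiles within ±5%) are the meaningful outputs, not the absolute errors.
- Specificity thresholds assume approximately Gaussian training scores; the
  χ² score-distance cut is asymptotic.
- The tolerance-interval implementation covers balanced designs only.
- JCAMP-DX support is a minimal XYDATA writer for interoperability, not a full
  reader/writer of the standard.
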