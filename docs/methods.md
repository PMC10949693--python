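# Methods

`specchem` implements a complete multivariate UV–vis quantification workflow
for two co-formulated drugs whose absorption spectra overlap strongly:
structured mixture designs, a synthetic spectra generator, four calibration
models, a full figures-of-merit suite, and quantitative sustainability
calculators. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Mixture designs

**Calibration.** The calibration set is the canonical 25-run five-level
two-factor cyclic design: each analyte visits the coded levels −2…+2 exactly
five times, the second analyte's code sequence is the first's shifted by one
run (cyclically), and the two coded columns are orthogonal with zero sum.
The canonical realization is hard-coded and re-validated at import
(balance, centering, orthogonality, cyclic-shift relation). Codes map to
concentrations by `c = center + code·step` with `center = (low+high)/2` and
`step = (high−low)/(n_levels−1)`; the default range is 10–30 µg/mL for both
analytes, so the design starts at the center point (20, 20) µg/mL.
Only the 5-level/2-factor case is implemented; other sizes are rejected
explicitly.

**Validation.** The external set is a stratified Latin hypercube sample:
each analyte's range is split into `n_strata` equal-width strata (13 by
default; a prime count avoids periodic resonance with the five calibration
levels and is recommended, not enforced), a random permutation assigns one
sample to each stratum per analyte independently, and positions within a
stratum are uniform. Equal-width strata encode a uniform prior over the
concentration range, which is the only prior consistent with a plain range
statement. Decimal rounding is off by default and treated as a lossy
post-step: it can collapse two samples to equal values and silently break
the one-per-stratum guarantee (the published realization of this design
shows exactly that artifact), so collapsed duplicates are recorded as
warnings and occupancy diagnostics always use the pre-rounding values.

## Synthetic spectra

The generator emulates two-component Beer–Lambert mixtures on a 200–400 nm
grid at 1 nm; modeling uses the 210–400 nm working range (191 points).
Each pure component is a sum of Gaussian bands in absorptivity units
(AU per µg/mL); mixtures mix linearly; the detector adds i.i.d. Gaussian
absorbance noise (default σ = 0.002 AU) and optionally a constant per-sample
baseline offset (default 0; an N(0, 0.005 AU) mode exists to exercise the
CLS intercept).

The default scenario fixes one component with a single band at 228 nm
(σ 13 nm) and the other with bands at 218 nm (σ 12) and 285 nm (σ 14), with
amplitudes chosen so the calibration mixtures peak between 0.2 and 1.5 AU
and the two pure spectra have cosine overlap ≈ 0.71 — strong overlap below
250 nm with one partially resolved band in the high 200s, qualitatively the
structure that motivates multivariate rather than single-wavelength
calibration. The band constants are fixed package constants, not fits to
any measured spectrum; no claim of spectral realism for any particular drug
pair is made. The noise level is a package constant chosen as a realistic
double-beam-instrument noise floor.

What the generator does *not* emulate: stray light, wavelength-axis drift,
heteroscedastic detector noise, nonlinear (high-absorbance) response, and
— in the default scenario — matrix absorption. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model, not
performance on real tablet extracts.

**Confined-signal scenario.** For wavelength-selection checks a second
scenario confines both analytes' bands to 240–300 nm and fills the rest of
the spectrum with six independent matrix absorbers (excipient-like
components with per-sample uniform amounts, bands at 216–392 nm). This is a
deliberate design choice: with pure i.i.d. noise outside the region, a
latent-variable regression is statistically flat in noise channels — we
measured region-only vs region+40-noise-window RMSECV as indistinguishable
at any σ from 0.002 to 0.1 AU, and paired single-window comparisons are coin
flips — so *no* selection procedure driven by cross-validated error can
enrich toward the region; worse, at n = 25 a selector can exploit
dataset-level chance correlations of noise channels. Independent matrix
absorption, in contrast, is both what real spectra contain in uninformative
regions and what gives selection a true gradient: with more interfering
directions than the fitness's latent-variable budget, every out-of-region
window measurably degrades prediction.

## Calibration models

All models reduce to the affine rule `ĉ = A_retained·B + b`, so one
`predict` serves all of them; training-set centering is folded into `b`,
and validation data are never re-centered on themselves.

**CLS with intercept.** Stage 1 estimates the pure-profile matrix S (plus an
offset row when the intercept is on) by least squares from `A = C·S`; stage
2 predicts a new spectrum by least squares against a basis of the estimated
pure profiles plus a ones row. The ones row (rather than the estimated
offset row, which is ≈ 0 when training data carry no baseline) is what makes
predictions invariant to a constant baseline on new spectra. An optional
boxcar smoothing window (odd widths, 5–29 nm scanned by cross-validation
under `window="auto"`) trades noise for resolution; on the default scenario
the scan usually selects no smoothing, which is expected at σ = 0.002 AU.

**PCR.** SVD of the mean-centered calibration spectra; concentrations are
regressed on the leading principal-component scores; because scores are
orthogonal the coefficient path over 1…k components is built incrementally.

**PLS.** PLS1 per analyte (closed-form NIPALS per latent variable: weight
`w ∝ X'y`, score `t = Xw`, loadings by regression on `t`, deflation of X and
y), with coefficients `B_k = W_k(P_k'W_k)⁻¹q_k`. Per-analyte extraction was
chosen because the workflow reports per-analyte latent-variable counts; a
joint PLS2 (iterative NIPALS with a convergence cap that raises with the
offending LV index) is available behind `variant="pls2"`. In the full-rank
limit both coincide with multiple linear regression on centered data (this
is oracle-tested, as is agreement with scikit-learn's PLSRegression).

**Latent-variable choice.** RMSECV over 1…10 LVs under venetian-blinds CV
(5 splits by default; leave-one-out and repeated random subsets are
available). The chosen count is the smallest whose RMSECV lies within one
standard error (per-fold RMSE spread / √folds) of the global minimum — a
parsimony rule that makes the choice robust to the near-flat error curves
past the true rank. When a CV training fold's rank is exhausted before the
scan ends, the coefficient path is padded with its last element so the scan
sees a flat curve rather than an error.

**GA-PLS.** Chromosomes switch non-overlapping windows of 2 wavelengths on
or off (a trailing odd wavelength forms a width-1 window). Fitness is the
cross-validated RMSECV of PLS on the active wavelengths, taking the best LV
count ≤ 3, under 5 random subsets × 2 iterations. The splits are drawn once
per generation and shared by every chromosome, so within-generation
comparisons are paired and split noise cancels — without this, a lucky
evaluation can freeze the elite and stall selection. Selection is
fitness-proportionate over ranks (rank r of n gets weight n−r), crossover is
two-point by default (single-point available), mutation flips genes
independently at 0.005, and one elite chromosome survives each generation.
The best-fitness trace reports the running best-so-far, which is
non-increasing by construction; the returned mask is the best-so-far
chromosome. The run stops when 80% of the population equals the current
best or at the generation cap (65 by default; population 40; 15% of windows
active at initialization — each initial chromosome draws its own 15%, with
an all-off chromosome repaired by activating one random window). The final
model restricts each analyte's spectra to its own mask, re-selects the LV
count (≤ 3) by venetian-blinds CV, and stores per-analyte masks with
coefficients zero outside them.

## Figures of merit

All statistics follow the printed-workflow conventions rather than textbook
defaults where the two differ:

- RSS, SSX, R² = 1 − RSS/SSX; PRESS, Q² = 1 − PRESS/SSX (SSX from the
  calibration set); RMSE family uses an n denominator; bias = mean residual.
- SEC uses bias-corrected residuals with n−1; BCMSEP = RSS/n − bias², which
  algebraically equals RMSE² − bias² ≥ 0 (asserted to 1e−12 on random
  vectors); consequently SEC² = n/(n−1)·BCMSEP.
- **RRMSEP% carries a 1/n prefactor** — `(√RSS/n)/ȳ·100` — by default; the
  conventional `RMSE/ȳ·100` is available via `form="conventional"`. The 1/n
  form is kept as the default for fidelity to the workflow being
  implemented; note it shrinks with n and is therefore not comparable
  across validation-set sizes.
- LOD = 3.3 σ/S and LOQ = 10 σ/S, with σ the residual standard error (n−2
  denominator) of the ordinary least-squares line of *measured* (y) on
  *predicted* (x) concentrations and S its slope; LOQ/LOD = 10/3.3 exactly.
- Recoveries are 100·found/nominal; %RSD uses an n−1 SD. One-way ANOVA
  across models' recovery lists reports F, p, and the critical F at
  α = 0.05 (via scipy); all-identical groups give F = 0, p = 1, and zero
  within-group variance with unequal means is flagged as infinite F.

Degenerate inputs (constant reference values, zero mean concentration) flag
the affected statistic as undefined instead of raising.

## Pipeline

`run_pipeline` executes design → simulation → trimming → fitting (CLS with
auto window, PCR, PLS, GA-PLS) → external validation → merit reports →
triplicate precision at 15/20/25 µg/mL → ANOVA → sustainability block, and
writes a JSON report, a flat merit CSV, and LV-scan/GA-trace plots. A single
master seed is expanded into per-stage seeds through `SeedSequence`
spawning; identical configurations produce byte-identical reports
(timestamps are deliberately absent). Q² for every model, including CLS and
GA-PLS, comes from genuine refits on each CV training split at the frozen
hyperparameters (window, LV counts, GA masks). Stage failures abort with
the stage name attached.

Standard-addition support predicts a base sample (mean of replicates) and
spiked samples, reporting `100·(found_total − found_base)/added` per spike,
with an explicit flag when all replicates of an analyte recover negative.

## Sustainability calculators

- Carbon footprint: Σ power (kW) · time (h) · emission factor (kg CO₂/kWh)
  over instruments, in kg CO₂ eq per sample.
- BAGI blueness: geometric mean of ten practicality criteria scored 1–10,
  reported ×10 on a 10–100 scale (ten equal scores s map to 10·s). The
  original tool's exact rounding is not reproduced, and the ×10 convention
  is documented rather than asserted as that tool's internal algorithm.
- RGB12 whiteness: each color group (red = validation, green =
  environmental, blue = economic/practical) is the unweighted mean of its
  four algorithm scores; whiteness is the mean of the three colors, with an
  optional weight vector defaulting to uniform.

Pictogram-style tools whose internal scoring is defined by external
software (NEMI, ComplexGAPI, AGREE) are not implemented; externally
produced scores can be carried as pass-through annotations in configs.

## Problem sizes and determinism

The test suite and the acceptance script run the study at desk scale: 25
calibration + 13 validation mixtures on 191 wavelengths, 50 noise seeds for
the latent-variable-selection frequency, 20 seeds for precision/validation
error envelopes and for the wavelength-selection checks. Every stochastic
stage consumes an explicit integer seed (numpy `default_rng`); fixed seeds
give bit-identical designs, spectra, GA masks, and reports.

## Known limitations

- Two analytes, five levels only; the general k-factor cyclic construction
  is not implemented.
- The CLS intercept absorbs constant baselines only; sloped or curved
  baselines require derivative/detrending preprocessing that is out of
  scope.
- GA selection quality is bounded by what cross-validated error can see: on
  data whose uninformative channels are pure i.i.d. noise the fitness is
  flat there, selected masks should not be over-interpreted as "informative
  regions", and at small n the selector can exploit dataset-level chance
  correlations (a general property of wavelength selection, documented
  above).
- The RRMSEP default (1/n prefactor) is non-standard; cross-study
  comparisons should use the conventional form.
- The one-standard-error parsimony rule is not infallible on i.i.d.-noise
  data at n = 25: in roughly one noise realization in ten, a third latent
  variable genuinely lowers the cross-validated error by more than one
  standard error through dataset-level chance correlations, and the rule
  then reports 3 instead of 2. The modal choice over repeated realizations
  is stable at 2. This is a property of cross-validated selection at small
  n, not of any particular CV scheme (venetian blinds and leave-one-out
  behave alike).
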