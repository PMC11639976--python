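# Methods

This note records the models, conventions, and design choices behind
`nirmold`, in the order the workflow runs. It documents what the code
computes and why the defaults are what they are; every number quoted as a
behaviour (accuracies, recovery rates) is one the test suite or
`scripts/acceptance.py` computes itself.

## Synthetic spectra generator

The generator (`nirmold.simulate`) emulates diffuse-reflectance NIR spectra
of a dried-peel matrix on the 511-point grid over 890–1720 nm used by
portable grating instruments. A spectrum of sample *i* in class
*c* ∈ {0, 1} is

    x_i(λ) = g_i · Σ_b (A_b + c·δ_b + j_ib) exp(−(λ−μ_b)²/(2σ_b²))
             + β_i0 + β_i1 u + β_i2 u² + ε_i(λ)

with `u` the wavelength rescaled to [−1, 1], `g_i = exp(N(0, 0.005²))` a
log-normal gain (multiplicative scatter), `j_ib ~ N(0, 0.002²)` per-band
amplitude jitter, quadratic baseline drift with coefficient sds
(0.005, 0.003, 0.002) AU, and i.i.d. instrument noise
`ε ~ N(0, 0.015²)` AU.

The default band layout places broad inert C-H bands at 1200 nm (σ = 45 nm,
A = 0.45) and 1620 nm (σ = 50, A = 0.40), and three narrower bands at
1380/1430/1480 nm (σ = 14 nm, A = 0.20/0.22/0.18) modelling the O-H/N-H
first-overtone complex. Only the latter three respond to class membership
(δ = 0.040/0.044/0.035 AU), so the informative region is 1350–1490 nm; the
returned truth mask marks grid points within one band width (±σ) of an
informative centre (54 of 511 points). One overtone-assignment caveat is
inherited from the application literature: sources disagree on whether
1200 nm belongs to the O-H or C-H overtone system; the generator follows
the band-table convention (1200 nm = C-H second overtone) without taking a
position.

Why these values. The defaults define the package's "high-SNR" study
regime, chosen so that the documented headline behaviours are properties of
the data-generating process rather than luck: (i) the per-band
delta-to-noise ratio ≈ 2.5 makes the classes separable to 100% by PLS-DA in
every pretreatment branch while no single wavelength separates them alone,
so wavelength selection has genuine work to do; (ii) the informative bands
are narrow (σ = 14 nm) because, under the normalized-covariance
randomization test, the asymptotic selection boundary sits near 1.05σ —
almost exactly the ±1σ truth mask — so selection precision and recall are
simultaneously achievable (with σ ≈ 25–30 nm bands the boundary falls
*inside* the mask and recall is capped near 0.7 no matter the effect size);
(iii) scatter and drift magnitudes (0.5% gain, ≤0.005 AU baseline terms)
are large enough that MSC/SNV/detrend visibly change the spectra but small
enough that a wavelength-selected model, which has lost its
scatter-reference wavelengths, still classifies perfectly. The second
derivative remains the deliberately weakest branch: differentiating twice
amplifies the 0.015 AU noise floor beyond what the band curvature always
overcomes, and at some seeds its branch accuracy is 98.5–99.2% rather than
100% — consistent with second-derivative pretreatment being the worst
performer on real data of this kind.

What the generator does *not* emulate: instrument line-shape and
wavelength-registration error, detector nonlinearity, water-activity band
shifts (class information is purely amplitude), non-Gaussian band shapes,
and batch drift between the pool and the "independent" batch (which differs
only by seed). Passing tests therefore show the algorithms are correct and
well-calibrated on an idealized but structurally faithful model of the
measurement; they do not certify performance on any real instrument.

## Pretreatments

All transforms are row-wise and pure; only MSC has fitted state.

* **SNV** uses the sample (n−1) standard deviation — fixed so exact tests
  are well-defined.
* **Detrend** removes a per-row least-squares polynomial (default order 2,
  the common NIR drift model) via an orthonormal QR basis, making the
  residual exactly orthogonal to the polynomial space.
* **Derivatives** are Savitzky–Golay, expressed per nanometre. Defaults:
  window 15 / polyorder 2 (first), window 21 / polyorder 3 (second). The
  wider second-derivative frame is the variance/bias compromise for a
  0.015 AU noise floor: at window 15 the noise amplification of the
  second-difference operator dominates the curvature signal of ~20 nm-wide
  bands.
* **CWT** is a single-scale Mexican-hat filter so the output stays one
  vector per spectrum; the sampled kernel is re-centred to exact zero mean
  (constants map to zero) and edges use symmetric reflection. Default
  scale 10 grid steps (~16 nm), matched to the width of typical analyte
  bands; a scale far above the band width acts as the wrong band-pass and
  suppresses the analyte signal relative to broad background structure.
* **MSC** regresses each spectrum on the mean calibration spectrum and
  inverts the fitted gain/offset. The reference is always the calibration
  mean, so application to test and later independent batches is
  well-defined; the dispatcher enforces that contract.
* **Min–Max** and **de-bias** are the usual range and offset
  normalizations; constant rows are rejected by name rather than silently
  propagated.

## Splitting and latent-variable selection

Kennard–Stone runs once per dataset on the raw spectra, so all pretreatment
branches share an identical 2:1 split and branch comparisons isolate the
pretreatment effect. Ties in the maximin step break to the lowest sample
index, which makes the procedure deterministic and testable against
exhaustive enumeration.

The latent-variable count is selected by MCCV (default 100 random 25%
holdouts) over k = 1..15: PRESS per k is averaged over holdouts and the
adjusted Wold's R rule stops at the first k whose successive PRESS ratio
exceeds 0.95 ("less than 5% improvement"). The threshold and cap are
configurable; 0.95 is the common adjusted-Wold convention and 15 covers the
usual NIR scan range. After wavelength selection the latent count of the
reduced model is re-selected by the same rule — the defensible default,
since the reduced spectra have different effective rank.

## PLS-DA conventions

PLS1/NIPALS with the 0/1 dummy response, threshold 0.5; `y` is not deflated
(standard PLS1, fixed for bit-reproducibility). Scores exactly at the
threshold are assigned to the undamaged class and counted. Rank exhaustion
raises an error naming the attained component. PCA (centred SVD, sign fixed
by making the largest-magnitude loading positive) is provided as an
unsupervised diagnostic only; no class decision derives from it.

## Wavelength selection

**RT.** The screening statistic is the normalized magnitude of the first
PLS weight vector, `|X_c' y_c|_j / ‖X_c' y_c‖`, compared per wavelength
against its distribution over label permutations with the add-one p-value.
Two facts drove this choice over the k-component regression coefficient:
a label-permuted PLS refit chases noise and inflates *every* coefficient
(measured ~3× the true fit's norm), so raw |b_j| comparison has no power at
all; and the k-component coefficient concentrates on band centres, so even
after per-fit normalization the band edges are never significant. The
normalized first-weight profile avoids both, and exchangeability of the
permuted labels makes the p-values exactly valid whatever the statistic: on
class-uninformative data the selected fraction is α (measured 0.051 at
α = 0.05 across seeds). Defaults n_perm = 1000, α = 0.05. The permutation
loop is one matrix product per batch of permutations, so RT costs
milliseconds. The selection may legitimately be empty (always when
α < 1/(n_perm+1)).

**CARS.** The retained-variable count follows the exponentially decreasing
schedule pinned at all p variables (iteration 1) and 2 variables
(iteration N, default 50). Each iteration refits PLS-DA on a random 80%
sample subset restricted to the retained set and keeps the top variables by
|b_j| up to the scheduled count — the competitive "survival of the
fittest", with the stochastic reweighting supplied by the Monte Carlo
resampling that perturbs the ranking between iterations. (A literal
probabilistic draw proportional to |b_j| was measured to exert too little
selection pressure: weakly ranked variables survive into the final subsets
and precision against the planted bands drops from ~0.9 to ~0.5–0.7.)
Every iteration's subset is scored by 5-fold cross-validated
misclassification on the full calibration set; the minimum wins, ties
broken toward fewer variables, then the earlier iteration. CARS is a
parsimony-driven optimizer: it returns the smallest subset that predicts
well (median ~6 variables on the default data), not a reconstruction of
the full informative region — high precision, deliberately low recall.
Wavelength interpretation with CARS belongs on scatter-corrected (MSC/SNV)
spectra; on raw spectra it legitimately retains scatter-reference
wavelengths that aid prediction but sit outside the analyte bands.

**MCUVE.** p artificial uniform-noise variables are appended, PLS-DA is
refitted on (default) 500 random 80% sample subsets, and each variable's
stability `mean(b_j)/sd(b_j)` over refits is thresholded at the largest
|stability| reached by any noise variable — so no appended noise variable
can ever be selected, and the cutoff adapts to the data. Zero coefficient
spread maps to +∞ stability with a warning counter. MCUVE keeps everything
whose coefficient is systematically non-zero — including
background-correcting wavelengths — which is why it retains by far the most
variables (median ~90+ on the default data, ordering CARS < RT < MCUVE).

## Validation

Q² = 1 − PRESS/SS_tot by 7-fold cross-validation (the usual software
convention) with folds redrawn, boundedly, until every training part
contains both classes. The permutation test refits at fixed k under 200
label shuffles (the conventional count), records calibration R²Y,
cross-validated Q², and |corr| with the original labels, and fits
least-squares lines of R² and Q² against correlation including the original
model at correlation 1. The validity flag is the Q²-intercept sign alone;
the R²-intercept is reported but not enforced, matching common practice
where the auxiliary R² rule is advisory. Because the original and permuted
statistics are exchangeable under the null, the original Q² falls inside
the permuted central 95% band with probability exactly 0.95 per dataset —
a binomial fact worth remembering when reading repeated-seed summaries of
that check.

## Pipeline

`run_pipeline` executes generate/load → KS split → per pretreatment: fit
state on calibration, transform all sets, select k by MCCV/Wold → per
selector: select wavelengths on calibration only, re-select k, refit →
confusion metrics on test and independent-test sets, optional permutation
test. All pretreatment state, latent counts, and selections are computed
from calibration rows only; the test suite asserts this by swapping the
held-out data and checking calibration artifacts are unchanged. Every
random element derives from one master seed via `SeedSequence`, and
identical configs give bitwise-identical reports.

## Problem sizes used in the checks

The shipped verification uses the full default conditions (400-spectrum
pool, 511 wavelengths, 100+100 independent batch) for the end-to-end
accuracy, selection-recovery, and permutation checks; the type-I and
null-distribution calibrations run 20 seeds at n_perm = 500 and 200
respectively, with the null-coverage check on a 200-point grid with 50
samples per class. Unit and property tests use reduced grids (64–200
points, 30–60 samples per class) chosen so the whole suite runs in about a
minute.

## Known limitations

* The RT statistic tests marginal (per-wavelength) association through the
  first PLS direction; wavelengths informative only through multivariate
  contrasts invisible to the covariance profile would be missed.
* CARS's cross-validated misclassification loss is coarse on well-separated
  data (many exact ties), which is precisely when the fewer-variables
  tie-break dominates; with RMSE as the loss CARS keeps far more variables.
  The misclassification convention was kept as the classification analogue
  of RMSECV.
* MCCV PRESS curves on derivative-pretreated spectra are flat, so the
  Wold rule sometimes picks a smaller k than the accuracy-optimal one;
  this is a property of the rule, not a bug, and the error-rate curve is
  reported alongside for inspection.
* The permutation test refits at the fixed, pre-selected k; selection
  uncertainty in k is not propagated into the permutation null.
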