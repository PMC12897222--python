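# Methods

`grainspec` implements a single-kernel near-infrared hyperspectral
workflow for detecting concealed insect infestation in cereal kernels
(the motivating case is immature rice weevil, *Sitophilus oryzae*,
developing hidden inside wheat). This note describes the models and
procedures, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Imaging model

A push-broom camera produces a raw count cube `I0` (rows x cols x 256
bands, 850-1700 nm). With a white reference cube `W` and a dark
reference cube `B`, reflectance is

    R = (I0 - B) / (W - B),    elementwise.

The denominator is floored at `1e-6` of the white dynamic range;
affected pixel-bands are counted in the log. Reflectance is not clipped
by default (a clip-to-[0, 1.2] flag exists) because clipping destroys
the linearity that the round-trip tests rely on.

Kernels are segmented from a grayscale image (a chosen band or the band
mean) by Otsu's threshold, then 4-connected components with a minimum
area; labels are numbered row-major by centroid so segmentation is
deterministic. Touching kernels are *not* split — the workflow assumes
kernels spaced on a plate, and a watershed step is out of scope. Each
kernel's spectrum is the arithmetic mean over its pixels, band by band
(the ROI mean spectrum).

ENVI raster I/O (plain-text header plus flat binary in `bil`/`bip`/
`bsq` interleave) is implemented in `grainspec.envi`; the on-disk
interleave is normalised to rows x cols x bands in memory.

## Preprocessing

Seven row-wise transforms plus the identity: Savitzky-Golay smoothing
and first/second derivatives (default window 11, polyorder 2 — common
NIR practice; derivatives are per nm, using the mean grid step with a
warning on non-uniform grids); multiplicative scatter correction (MSC:
per-row OLS `x ~ a + b*ref`, corrected to `(x - a)/b`, reference = the
*training-set* column mean, frozen for test rows to prevent leakage);
standard normal variate (SNV, sample sd, ddof = 1 — the ddof
convention holds package-wide); polynomial detrending (default order
2); and asymmetric-least-squares baseline correction (penalised second
differences, smoothness 1e5, asymmetry p = 0.01, 10 reweighting
iterations). SG edge samples are produced by a polynomial fit over the
terminal window rather than reflection padding, so exactness
guarantees apply to interior points only.

A practical note on ALS baselines: the converged baseline tracks the
spectrum from below only up to a reweighting bias of order
`p * (peak mass)` — a few 1e-3 on unit-scale spectra — so "baseline
below the signal" holds at that tolerance, not at machine precision.
The tests assert it at 0.25% of the peak height.

## PLS core and RMSECV

All wavelength selectors are driven by a single-response PLS (PLS1)
regression of the class code (healthy = 0, infested = 1) on the
column-centred spectra, computed by NIPALS. For one response NIPALS is
non-iterative: each component's weight vector is the normalised
covariance `X'y`, after which `X` is deflated. One fit at `A_max`
yields the coefficient vectors of every truncation `1..A_max`
(`b_a = W (P'W)^{-1} q` cumulated), which makes cross-validation cheap
inside the Monte-Carlo selectors. Components are dropped when the
residual covariance vanishes (exact-fit or rank-deficient data).

RMSECV is the *pooled* root-mean-square of all out-of-fold residuals
(not a mean of per-fold RMSEs). Folds are class-stratified: samples of
each class are shuffled with a seeded generator and dealt round-robin,
so fold sizes differ by at most one and every training fold sees both
classes whenever possible. A training fold that still ends up
single-class falls back to a constant prediction with a warning.

## Wavelength selection

All four selectors and their SPA-chained combinations score candidate
subsets by the pooled RMSECV above, and all are bit-reproducible given
`(X, y, params, seed)`.

**CARS** (defaults: 50 Monte-Carlo runs, max 8 latent variables,
10-fold CV). Run `i` fits a PLS model (A chosen by RMSECV, capped) on a
random 80% sample subset, weights each surviving band by its normalised
|coefficient|, and enforces the exponentially decreasing retention
schedule `r_i = a e^{-k i}` with `r_1 = 1` and `r_N = 2/B` (`a`, `k` in
closed form; retained count `ceil(B * r_i)`). The enforced count is
reached by adaptive reweighted sampling: weighted draws with
replacement (5x oversampling), unique survivors, truncated by
descending weight. The subset with the lowest full-data RMSECV over
all runs wins. A run that leaves fewer than two bands ends the
schedule; subsets already evaluated still compete.

**SPA** (defaults: subset sizes 5..min(30, N-2)). From every starting
band a forward chain is grown: at each step all unselected bands are
projected onto the orthogonal complement of the selected bands' span
(modified Gram-Schmidt on the raw, uncentred columns) and the
largest-residual-norm band is added, ties to the lowest index. Every
(start, length) prefix is scored by PLS-RMSECV and the global minimiser
returned. SPA is deterministic apart from the CV plan's fixed seed.

**UVE** (defaults: max 8 latent variables, 10-fold deletion groups,
B artificial noise bands, threshold quantile 0.99). The spectra are
augmented with uniform noise bands scaled to 1e-10 of the data
magnitude; PLS models are refitted leaving out one fold at a time; each
band's stability is `c_j = mean(b_j)/sd(b_j)` over the refits, and real
bands survive when `|c_j|` exceeds the chosen quantile of `|c|` over
the noise bands. The deletion-group models are fitted at the full
`max_pc` order rather than an RMSECV-chosen one. This is deliberate:
with the RMSECV-optimal order (typically 2 on these data) the
coefficient vector lives in a low-dimensional smooth subspace, every
band inherits stable chance structure from it, and roughly a fifth of
the uninformative bands beat the noise threshold; at order 8 the
coefficients localise onto the informative bands and false retention
drops to a few bands in 246. Bands with zero coefficient variance get
infinite stability (always kept) with a warning.

**IRIV** (defaults: max 40 latent variables, 11-fold CV, 500 binary
rows, alpha 0.05). Each round draws a random binary inclusion matrix
(inclusion probability 0.5, rows forced to include at least two
bands), scores every row's band subset by RMSECV, and classifies each
band by the difference of mean RMSECV between rows excluding and
including it (`DMEAN > 0` means inclusion helps) with a two-sided
Wilcoxon rank-sum p-value: strongly informative (`DMEAN > 0`,
`p < alpha`), weakly informative (`DMEAN > 0`, `p >= alpha`),
uninformative, or interfering. Strong and weak bands are retained;
rounds repeat until nothing is dropped; a final backward elimination
removes any band whose deletion lowers the subset RMSECV. The retained
set is non-increasing by construction, so the procedure terminates.

**Chaining** re-runs SPA on the column subset surviving a first-stage
selector and maps indices back to the original grid, giving the
`cars_spa`, `uve_spa` and `iriv_spa` combinations; chained selections
are subsets of the first stage by construction.

## Partitioning, classifiers, evaluation

Samples are split 7:3 by the Kennard-Stone maximin algorithm on the
modelling spectra: start from the globally most distant pair
(Euclidean), repeatedly add the sample maximising its minimum distance
to the selected set, distance ties to the lowest row index. At the
full sample scale (N = 589) this yields 412 calibration / 177 test samples.

Four classifiers, with 5-fold cross-validated tuning on the
calibration set only: SVM with RBF kernel, cost tuned over
{0.625, 1.25, 2.5, 5, 10} (centred on 2.5) with `gamma='scale'`;
decision tree (Gini, at most 20 splits — `max_leaf_nodes = 21`); KNN
(Minkowski distance, uniform weights, K from {3, 5, 7, 9, 11, 15, 20});
random forest (200 trees, minimum leaf size 5, seeded). Tuning picks
the candidate with maximal pooled CV accuracy, breaking ties by Cohen's
kappa and then by the smaller parameter value — one concrete reading of
"jointly considering accuracy and kappa". The estimators themselves
come from scikit-learn; the contract here is the hyperparameters, the
tuning rule and determinism.

Evaluation treats infested as the positive class and reports the 2x2
confusion matrix with accuracy, precision, recall, F1 (positive class)
and Cohen's kappa `(p_o - p_e)/(1 - p_e)` with `p_e` from the
marginals. The SVM decision threshold is 0; no probability calibration.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

    x = gain * (base + label*effect + baseline) + offset + noise

* `base`: a smooth reflectance profile (broad hump with Gaussian
  absorption dips near 970, 1200 and 1450 nm, values ~0.25-0.65),
  standing in for a wheat kernel's water/starch/protein NIR signature.
* `effect`: raised-cosine bumps inside configurable windows — defaults
  980-1100, 1200-1300 and 1400-1600 nm at 0.02 reflectance units, the
  regions and a plausible magnitude of the infested-vs-healthy
  difference. `with_planted_bands` narrows the windows to single bands
  for unambiguous selector-recovery scoring.
* scatter: per-sample lognormal gain (sigma 0.05) and additive offset
  (sd 0.01), the multiplicative/additive distortion MSC targets;
* `baseline`: a per-sample degree-2 polynomial drift (coefficient sd
  0.005), exercising detrend and baseline correction;
* `noise`: white, sd 0.005 per band — a mid-range figure for
  single-kernel SWIR instruments.

Defaults mirror the full acquisition scale: 220 healthy + 369 infested samples,
256 bands over 850-1700 nm. Ground truth (labels, informative band
indices, per-sample gain/offset, noiseless class means) is returned so
every downstream method can be scored exactly. `generate_cube` paints
per-kernel spectra into non-overlapping ellipses of a raw-count cube
with constant white/dark references, exercising the full imaging path;
at zero pixel noise the correction-segmentation-extraction round trip
inverts the painting exactly.

What the generator does **not** emulate: wavelength-dependent scatter
(gain is flat across bands, so MSC's single multiplicative constant is
exactly right for it), detector nonlinearity and striping, touching or
overlapping kernels, orientation effects (crease up vs down),
developmental-stage chemistry (a time point is just an effect
amplitude), and between-cultivar variation. Passing tests therefore
show the algorithms are implemented correctly and behave as intended
under the assumed structure — not that the same accuracies would be
reached on real kernels.

Two structural consequences of the multiplicative model are worth
knowing when interpreting recovery tests. First, MSC with the pooled
column-mean reference transfers a trace of the class effect into the
per-row fitted gain, so after correction *every* band carries a weak
class signal; with many bands this is negligible, but when the planted
effect occupies a large fraction of a short spectrum (e.g. 2 of 8
bands) it makes nominally uninformative bands genuinely weakly
informative. Small-grid recovery examples therefore disable scatter.
Second, exact MSC inversion of the scatter (`corrected == truth` to
1e-8) holds when each row is exactly affine in the reference — i.e.
no class effect, no baseline drift, reference = the true base profile —
and the tests assert it in that configuration.

## Experiment grid

`run_experiment` executes preprocessing x selector x classifier
combinations with a leakage-safe protocol: split first; preprocessing
statistics (the MSC reference) fitted on calibration rows only;
selection run on the preprocessed calibration rows only; classifier
tuning by 5-fold CV inside the calibration set; one final evaluation on
the untouched test rows. A failing combination is marked failed and the
grid continues. Every artifact embeds a SHA-256 hash of the
configuration, and `summarize` refuses to merge tables with different
hashes. An audit test asserts the selector never sees test rows.

## Problem sizes used in the checks

The acceptance checks run at the generator's default scale: ten seeds
of N = 589 x B = 256 for CARS and UVE recovery and for the end-to-end
MSC -> CARS -> SVM pipeline (paired against raw spectra on the same
split), and ten seeds of N = 589 x B = 30 with five planted bands for
IRIV, whose binary-matrix resampling dominates the runtime at about
15 s per seed. The whole suite completes in a few minutes on one CPU.

## Known limitations

* Touching kernels are not separated; segmentation assumes spaced
  kernels on a plate.
* The UVE noise-augmentation threshold calibrates "chance stability"
  only; on spectra with strong shared structure (uncorrected scatter)
  it legitimately retains many bands, as scatter-cancelling
  coefficients are genuinely stable.
* SPA evaluates candidate subsets with PLS-RMSECV (consistent with the
  selection objective elsewhere); an MLR-based variant is a flag away
  but not the default.
* The classifiers are thin wrappers over scikit-learn; MATLAB-style
  semantics (e.g. `KernelScale` auto) are approximated by the closest
  scikit-learn equivalents (`gamma='scale'`).
* Class coding {0, 1} for the PLS regressions is a convention; centred
  internally, its scale only affects RMSECV units, not selections.
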