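# Methods

`ovotrace` implements a complete chemometric pipeline for classifying the
geographic origin of intact eggs from visible/near-infrared transmission
spectra. This note records the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

A transmission spectrum is a non-negative intensity vector sampled on a
shared wavelength axis; the physically valid window for a tungsten-halogen
source read through a 200–1100 nm spectrometer is 400–1100 nm, and all
pipelines crop to it first. Origin labels are integer codes fixed as
0 = Sichuan, 1 = Jiangsu, 2 = Henan. Intensities are treated as arbitrary
non-negative units: nothing in the pipeline assumes counts, transmittance,
or absorbance, and preprocessing operates on whatever scale is supplied.

## Preprocessing

Exactly one method is applied per pipeline configuration:

* **SNV** standardizes each spectrum to mean 0, sample standard deviation 1
  (ddof = 1). It removes per-sample gain and offset exactly, so a noiseless
  scatter family (affine images of one template) collapses to a single
  vector.
* **MSC** regresses each spectrum on a reference by ordinary least squares,
  `x ≈ a + b·ref`, and returns `(x − a)/b`. The reference defaults to the
  mean spectrum of the *training* partition and is stored with the fitted
  pipeline, so held-out and online samples are corrected against the same
  reference (no test-set leakage). Fits with `|b| < 1e-12` are reported as
  degenerate rather than silently amplified.
* **Savitzky–Golay** smoothing uses `scipy.signal.savgol_filter` with
  defaults window 11 points, polynomial order 2, derivative 0 — conventional
  settings for ~1400-point Vis/NIR spectra. Edges are handled by fitting the
  polynomial to the edge windows (`mode="interp"`), so output length equals
  input length and wavelength indexing stays stable for selection.

## Wavelength selection

Both selectors score candidate subsets by cross-validated RMSE of a linear
calibration on the numeric origin codes (0/1/2). Ordinal encoding of the
three classes as one response is the standard single-response formulation
for selection on classification data; a one-response-per-class variant would
be a straightforward extension but is not implemented. Folds are stratified
by class and derive from the run seed.

**SPA** grows a chain from every starting wavelength: at each step each
remaining column is replaced by its component orthogonal to the span of the
selected set (modified Gram–Schmidt), and the column with the largest
residual norm joins the chain. Columns whose residual norm falls below
`1e-10` of the largest column norm are treated as collinear and excluded,
which is what prevents duplicate columns from being co-selected. Every
(start, size) prefix is scored by K-fold CV RMSE (default K = 10, matching
the CARS setting); the score is computed from per-fold Gram matrices with a
relative ridge of `1e-10` for numerical stability, which keeps the scan over
all 1401 starting wavelengths tractable (seconds to tens of seconds). The
chosen subset minimizes the RMSE-versus-size curve, ties going to the
smaller size.

**CARS** runs a Monte Carlo loop (default 100 runs, 10-fold CV, 80% sample
fraction, PLS with at most 10 latent components). Per run: fit PLS on a
random subsample restricted to the surviving wavelengths; convert
coefficients to importance weights `w_i = |k_i| / Σ|k_j|` (the absolute
value is required — signed weights would make sampling ill-defined);
eliminate exact-zero weights; force-remove down to the exponential decay
count `r_i·p` with `r_i = a·e^{−k·i}` fixed by `r_1 = 1` and `r_N = 2/p`;
then resample the survivors with weighted draws with replacement, keeping
the unique draws (classical adaptive reweighted sampling — a
without-replacement draw of the same count would be a no-op). Forced removal
and resampling are skipped at runs where the schedule retains every
survivor, so the retained-count trace starts at the full variable count.
RMSECV of each run's survivors is measured on the *full* training table (the
Monte Carlo subsample is used only for the weights), and the best run's set
is returned.

On the synthetic benchmark CARS characteristically keeps large subsets
(RMSECV is genuinely minimized by redundant informative channels on this
easy, low-noise problem); its ability to isolate a small number of truly
informative variables is instead demonstrated on a sparse-signal simulation
(3 informative of 50 columns, SNR 20, response cut into the three classes),
where all three planted variables are recovered in ≥ 90% of seeded
repetitions.

The PLS engine is `sklearn.cross_decomposition.PLSRegression` with
`scale=False`, exposed as a flat coefficient vector plus intercept; with as
many components as (full-rank) columns it reproduces ordinary least squares,
which the tests verify.

## Classifiers

* **Random forest** — bagged `DecisionTreeClassifier` trees (default 10
  trees of depth 2, `sqrt(M)` features per split, no pruning), assembled
  explicitly so that prediction is a literal majority vote with ties broken
  toward the smallest class code. Single-class training data yields a
  constant predictor with a warning.
* **RBF SVM** — `sklearn.svm.SVC` with kernel `exp(−‖x−z‖²/σ²)` and
  one-vs-one voting over the three class pairs. Features are standardized
  with statistics fitted on the training partition (RBF distances are
  scale-sensitive); σ defaults to the median pairwise training distance,
  C defaults to 1. The fitted decision function is exactly the
  support-vector expansion `Σ aᵢ* K(x, zᵢ) + b*`, which a test evaluates
  manually against the fitted model.
* **Outer-product CNN** — each sample's selected-wavelength vector `x`
  becomes the rank-1 matrix `S = x xᵀ` (symmetric, PSD, trace `Σxᵢ²`), fed
  to a small 2-D network: 3×3 conv with 96 kernels (same padding) → batch
  norm → ReLU → 2×2 max pool stride 2 → 1×1 conv, 192 kernels → BN → ReLU →
  1×1 conv, 384 kernels → BN → ReLU → fully connected 32 (ReLU) → fully
  connected 3 → softmax. There are exactly three batch-norm layers (after
  the convolutions); the first fully connected layer uses a plain ReLU.
  Note that for a single sample S is rank-1, not a covariance estimate; the
  transform is used purely as a 2-D embedding.

  The network is implemented directly on NumPy arrays with hand-written
  backpropagation (im2col for the 3×3 convolution, per-channel batch norm
  with running statistics, ε = 1e-5, momentum 0.1; max-pool ties share
  gradient equally). Inputs are at most ~132×132, so no GPU or autograd
  framework is needed, and runs are bit-reproducible from the seed (He
  initialization and batch shuffling both derive from it). Training is
  mini-batch SGD on softmax cross-entropy with learning rate 1e-4, batch
  size 4, and up to 300 epochs; momentum is available but off by default,
  and there is no early stopping. Same padding keeps every subset size from
  the smallest SPA selections (8) to the largest CARS selections (~132)
  valid under one rule; the only hard requirement is ≥ 2 selected
  wavelengths so the pooling layer has output. Batch-norm uses standard
  train/eval mode switching; inference uses the running statistics.

## Evaluation metrics

Per class (one-vs-rest): precision `P = TP/(TP+FP)`, recall
`R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, and classification error `E = 1 − R`.
Overall accuracy is micro accuracy (total correct / total evaluated) — the
per-class binary form `(TP+TN)/total` is also reported, but the overall
figure published for this kind of table is reproducible only under the
micro reading. All percentages round half-up to 2 decimals; E is derived
from the already-rounded R so that `E + R = 100` holds exactly even when
the unrounded recall sits on a binary-exact half (e.g. 96.875). A class
with no predicted positives has undefined precision, reported as `None`
with F1 omitted, never as a silent zero. A reconstruction utility recovers
overall accuracy from per-class recalls and supports, requiring each recall
to imply an integer correct count within the rounding tolerance of a
2-decimal percentage (`0.005·support/100`).

## Synthetic data generator

No public duck-egg spectra exist, so the generator emulates the reported
qualitative structure; every magnitude is the package's own choice and is
configurable. A spectrum is built as

    baseline(w) · level_c(w) · (1 − d₁·g₇₀₀(w) − d₂·g₈₀₀(w))

with a broad transmission bell (floor 0.15, center 750 nm, width 180 nm), a
class-level multiplier confined to the 550–900 nm band by sigmoid shoulders
(defaults 0.93 / 1.07 / 1.00 for classes 0/1/2, giving the band-mean
ordering Jiangsu > Henan > Sichuan), and two Gaussian absorption dips at
700 and 800 nm (widths 25 and 30 nm). The class-dependent 700:800 depth
ratio (defaults 0.5 / 1.5 / 1.0, ordered Jiangsu > Henan > Sichuan)
reallocates a fixed total absorbed area (base depth 0.25) between the two
dips, so the ratio signature lives only at the peaks and does not perturb
the band means. Each sample then receives a multiplicative scatter slope
(uniform 0.85–1.15), an additive offset (sd 0.02), and per-point Gaussian
noise (default sd 0.01, i.e. 1% of the baseline amplitude — the "moderate"
preset; ≤ 2% is considered moderate). Outputs are clipped at zero.

The default benchmark splits 351 samples (110/130/111 per class) into
182 training / 79 test / 90 online-validation tables with the per-class
design 56/70/56, 24/30/25, 30/30/30; fractional splits use
largest-remainder stratification.

What the generator does *not* emulate: instrument line shape, wavelength-
dependent noise, shell-thickness covariates, temperature drift, or any
absolute intensity scale. The benchmark is separable by construction, so
pipeline tests demonstrate correctness of the machinery (and perfect
separation in the zero-noise limit), not field performance on real eggs.

A design consequence worth noting: because the class-level ordering over
550–900 nm is itself informative (as it is in real spectra), wavelength
selectors legitimately mix band and edge wavelengths with peak wavelengths
on the default benchmark. The property "selected wavelengths concentrate at
the planted absorption bands" is therefore asserted under a configuration
with near-neutral class levels, where the dips are the only material class
signature.

## Problem sizes and runtimes

The default test and acceptance runs use the full 1401-point axis with the
182/79 benchmark split; SPA scans all starts with `max_vars = 12` (tens of
seconds), CARS uses its defaults (seconds on selected subsets), and the CNN
is trained for 50 epochs in the end-to-end checks (its classification on
this benchmark converges long before the full 300-epoch schedule; the
300-epoch default remains available for real data). The sparse-signal CARS
simulation uses 90 samples × 50 columns × 50 runs × 20 repetitions.

## Known limitations

* Selection treats the three origins as an ordered numeric response; for
  problems where class codes are not meaningfully ordered, selection quality
  may degrade even though classification itself is unaffected.
* The CNN trains on CPU in NumPy; it is entirely adequate for ≤ 132-wide
  inputs and a few hundred samples but is not intended for large images.
* Undefined precision propagates as `None`; downstream consumers averaging
  per-class F1 must handle omitted entries.
* CARS run-to-run survivor sets are nested only in expectation; the
  retained-count trace can dip below the decay schedule because adaptive
  reweighted sampling keeps unique draws.
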