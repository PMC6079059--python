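# Methods

This note documents the models, algorithms and numerical choices behind
`ramancharm` — what each stage assumes, which knobs matter, and what the
synthetic benchmark does and does not establish about real data.

## The problem

A Raman hyperspectral image of a single cell is a `(rows, cols, k)` array:
every pixel carries a ~1024-point Raman spectrum (600–3100 cm⁻¹).  Three
bands proxy major cellular compounds — 750 cm⁻¹ (cytochrome c), 1687 cm⁻¹
(amide I, protein), 2850 cm⁻¹ (CH₂ stretch, lipid).  Cell types can be told
apart either by their *average* spectrum over the cell area, or — often
better — by the *spatial pattern* in which each compound is distributed.
The package implements both routes and their fusion:

I.   average spectrum → standardize → DA-PC classifier;
II.  per-band compound images → 1025 image descriptors per channel
     (3075 per cell) → Fisher ranking → top-N → DA-PC;
III. independent PC blocks from (I) and (II), pooled, stepwise-selected,
     classified together.

## Spectral preprocessing

Fixed order, each step logged in a `PreprocessingReport`:

1. **Cosmic-ray removal.**  Per pixel spectrum, a running median (window 7,
   reflected edges) along the spectral axis; a channel is replaced by the
   local median when its residual exceeds 8 robust sigmas (1.4826 × median
   absolute residual, with a tiny absolute floor) *and* both neighbouring
   residuals are below half its magnitude.  The second condition matters:
   spikes are essentially single-channel, while the apex of a genuine Raman
   band — whose residual from the running median can also exceed the
   threshold when the band is only 1–2 channels wide on a coarse grid —
   always keeps a tall neighbour and is left untouched.  Without it the
   filter measurably clips bright band apexes and distorts downstream
   amplitude maps.  Multi-channel spike clusters require a second pass with
   a wider window.
2. **Background subtraction** of a supplied spectrum or the mean over a
   blank region.  Negatives are retained; clamping would bias later fits.
3. **Baseline correction.**  Default `modpoly` (iterative modified
   polynomial fitting, Chebyshev basis, degree 5, ≤40 iterations,
   tolerance 1e-6 of the data scale): fit, clip the working spectrum to the
   fit, refit — peaks are progressively excluded and the fit settles on the
   smooth autofluorescence background.  `als` (asymmetric least squares,
   λ=1e5, p=0.01, 10 reweighting iterations) is provided for users who want
   to match a Whittaker-style baseline.  Both are standard for Raman; the
   package default is modpoly because it has no smoothness tuning parameter
   with units.
4. **Normalization.**  Default per-pixel L2; `area` (sum of the positive
   part) and `peak` (max in a reference band) offered.  Downstream features
   are standardized anyway, so the choice is low-risk; L2 is the most
   robust to residual baseline.

Cropping of the spectral axis (some studies analyse a sub-range of the
detector) is exposed as configuration and off by default.

## Compound images

Per pixel, `I(ν) = A·exp(−(ν−c)²/2σ²) + b₀ + b₁ν` is fit over a ±40 cm⁻¹
window around the band center; the pixel value is the amplitude `A`
(integrated area `A·σ·√2π` optional).  The fit is a variable-projection
scheme: the linear block `(A, b₀, b₁)` is solved exactly (with `A ≥ 0`
enforced by refitting the baseline alone) for each candidate `(c, σ)`; the
nonlinear pair is located on a deterministic grid (up to 12 centers ×
6 sigmas) and polished by damped, bounded Gauss–Newton, all pixels
simultaneously.  Convergence is declared on a data-scale cost plateau or a
first-order (projected-gradient) stationarity check; the rare non-converged
pixel falls back to `max(0, peak-channel − window median)` and is flagged.
There is no randomness anywhere in the fit, so reconstruction is
reproducible bit for bit.

Bounds: `A ≥ 0`, center inside the window, `σ ∈ [0.5·channel spacing,
window width]`.  A window of ±40 cm⁻¹ isolates each default band while
tolerating its neighbours; with 1024 points over 2500 cm⁻¹ it holds ~33
channels (the minimum accepted is 5).

Cell segmentation thresholds the protein and lipid channels (Otsu per
channel by default, fixed thresholds accepted), ORs the maps, labels
8-connected components, discards components under 50 px, and returns masks
ordered by area.  Manual pixel additions are merged by OR.  Before feature
extraction an image is zeroed outside its mask and cropped to the mask
bounding box — this removes neighbour signal and makes descriptors
translation invariant by construction.

## The descriptor bank (1025 per channel)

Descriptors are computed on the raw image and five transforms of it:
log-magnitude 2-D FFT, a symlet-5 wavelet detail image (level ≤ 2), the
order-20 2-D Chebyshev coefficient-magnitude image, and the two compound
transforms (wavelet of Fourier, Chebyshev of Fourier).  Eleven families
run on designated transforms:

| family | values | transforms | total |
|---|---|---|---|
| Chebyshev coefficient histogram | 32 | raw, FFT | 64 |
| Chebyshev–Fourier coefficient histogram | 32 | raw, FFT | 64 |
| comb first-four moments | 48 | all 6 | 288 |
| edge statistics | 28 | raw | 28 |
| Gabor energies | 7 | raw | 7 |
| Haralick co-occurrence (14 stats × mean/range) | 28 | all 6 | 168 |
| multi-scale histograms (3+5+7+9 bins) | 24 | all 6 | 144 |
| object statistics | 34 | raw | 34 |
| Radon projection histograms | 12 | raw, FFT, Chebyshev, Chebyshev(FFT) | 48 |
| Tamura textures | 6 | all 6 | 36 |
| Zernike moment magnitudes (order ≤ 15) | 72 | raw, FFT | 144 |

Total: exactly **1025**; the manifest (name, family, transform, fixed
order) is generated deterministically and asserted on import — a length
mismatch is a fatal consistency error, never a silent truncation.  Three
channels concatenate to **3075** in fixed (cytochrome, protein, lipid)
order with channel-prefixed names.

Conventions that change values and are therefore frozen here:

- Haralick: 8-bit min–max quantization over the crop, co-occurrence
  distance 1, four directions, symmetric and normalized; mean and range of
  each statistic across directions.  The 14th statistic is the *difference
  average*, not the maximal correlation coefficient, whose per-direction
  eigendecomposition dominates runtime at six transforms per channel for a
  negligible gain in information.
- Zernike: orders n ≤ 15 (72 (n,m) pairs), computed on the disk inscribed
  in the crop, magnitudes normalized by the in-disk absolute mass.
- Gabor: seven frequencies 0.05–0.35 cycles/px with a fixed σ = 2.5 px
  envelope (compact kernels at all frequencies); feature = band energy
  relative to image energy.
- Tamura: contrast σ/kurtosis^{1/4}; directionality = Σh² of the 16-bin
  gradient-orientation histogram; coarseness from best-of-scale box
  differences at 2¹…2⁵ px plus a 3-bin log-size histogram.
- Non-finite descriptor values are replaced by 0 and logged, so
  standardization never fails on a degenerate image.
- Images are **not** resampled to a common size; size-sensitive features
  intentionally capture cell size.
- Positive intensity rescaling leaves quantization-based textures unchanged
  on homogeneous transforms (raw, wavelet, Chebyshev); the log-magnitude
  FFT transform is deliberately not homogeneous.

## Feature weighting and selection

Features are standardized to mean 0 / sd 1 with *training-row* statistics
(sample sd, ddof = 1); zero-variance columns map to 0 and are flagged.  The
Fisher discriminant score of feature *f* over classes *c = 1…C* is

    W_f = [ 1/(C−1) · Σ_c (m_fc − m̄_f)² ] / [ 1/C · Σ_c v_fc + ε ],

between-class variance of the class means over the mean within-class
variance, ε = 1e−12 guarding perfect separators (scores are reported raw,
unbounded).  Ranking is by descending score with ties broken by manifest
order.  By default scores are computed on training rows only; an opt-in
`rank_on_all` mode uses all rows for users who accept the leakage.  The
top-N sweep over {10, 25, 50, 75, 100, 200, 300} reports accuracy, entropy
R² and −2 logLikelihood per N on train and test.

## The DA-PC classifier

1. **PCA** by SVD of the column-centered training block; `min(n−1, p)`
   components; sign fixed by making the largest-magnitude loading element
   positive.
2. **PC gate.**  Forward stepwise at α = 0.001: for each candidate PC the
   partial Wilks' Λ given the already-selected PCs, Λ_partial =
   Λ(sel∪{j})/Λ(sel) with Λ(V) = det W_V / det T_V, converted to the exact
   F for one added variable, F = (1−Λ)/Λ · (N−g−s)/(g−1) on (g−1, N−g−s)
   df.  For a single added variable the Wilks and Hotelling–Lawley partial
   tests coincide, so both criterion names run the same stepwise test; a
   marginal one-way ANOVA criterion is also available.  Selection stops
   when no candidate reaches α; an empty selection is an error — the
   discriminant refuses to fit on zero components.
3. **Quadratic DA.**  Per-class mean and sample covariance, doubly
   regularized.  First, Friedman-style shrinkage toward the pooled
   covariance, Σ_c ← (1−λ)Σ_c + λ·Σ_pooled with λ = 0.25: with only a
   handful of training cells per class the raw class scatter can
   underestimate whole directions, and a too-tight class then rejects its
   own held-out members (Mahalanobis distance explodes) while a wider
   neighbour absorbs them; borrowing strength from the pooled estimate
   stabilizes exactly those directions while keeping the covariances
   class-specific — the discriminant stays quadratic (λ = 1 would recover
   linear DA).  Second, shrinkage toward the diagonal,
   Σ_c ← (1−γ)Σ_c + γ·diag(Σ_c); γ starts at 0.1 and escalates through
   {0.3, 0.5, 1.0} until every class condition number is below 1e8
   (singularity at γ = 1 is a fatal error with a diagnostic).  Priors are
   the training class proportions.
4. **Membership probabilities.**  p_c(x) ∝ π_c |Σ_c|^{−1/2} exp(−d_c/2)
   with Mahalanobis d_c = (x−μ_c)ᵀΣ_c⁻¹(x−μ_c), normalized; prediction is
   the argmax, ties broken by class order.

Metrics: accuracy with confusion matrix; −2 logLikelihood = −2 Σ ln p(true)
with probabilities floored at 1e−12; entropy R² = 1 − ℓ_model/ℓ_null where
the null emits training class proportions.  A priors-only model therefore
scores R² = 0 and, with three balanced classes, −2logL = 2n·ln 3; a
perfect model scores 0 and R² = 1.

The hold-back split is stratified (round(0.25·n_class) test cells per
class, seeded); a `day_tag` mode holds out whole acquisition batches to
emulate a test day measured independently.

**Fusion** fits PCA separately on the standardized spectral block and the
standardized image block, standardizes both blocks' PC scores to unit
training variance, pools them tagged by block, and runs the same joint
stepwise gate and QDA.  The result reports how many selected components
came from each block.  A block that is an exact copy of the other
contributes only collinear candidates, which the det-ratio test rejects, so
duplicated information cannot enter twice.

Comparators (PLS-DA with 2 components, K-means with 3 clusters mapped to
labels by maximum agreement, RBF SVM) are thin adapters over scikit-learn
under venetian-blind (interleaved) 10-fold cross-validation; they return
accuracy only, since they do not produce membership probabilities.

## The synthetic cohort

Defaults mirror the acquisition the pipeline targets: 3 classes × 24 cells,
a 40 μm field at 120 × 120 px, 1024-point spectra on 600–3100 cm⁻¹.  Each
cell is a perturbed-ellipse blob (radius 0.30 × field ± 8%, four random
harmonics).  Compound maps inside the blob:

- **cytochrome** — Gaussian granules, Poisson count, per-class (count,
  σ_px, amplitude);
- **lipid** — sparse droplets, same construction;
- **protein** — smoothed blob interior times a multiplicative Gaussian
  random field whose correlation length and depth are per-class parameters
  (the "smoothness" of the protein distribution).

The three default classes keep granule/droplet *mass* (count × σ²) equal
while differing strongly in granularity — many-small vs few-large vs
intermediate — so average spectra are nearly identical but textures are
distinct: exactly the regime in which image descriptors should beat the
average spectrum.  The protein channel differs in texture scale/depth
(1.5/0.12, 4.5/0.30, 2.6/0.20) and mildly in amplitude (0.54/0.60/0.66),
leaving the spectra similar but not degenerate.  Per-bump size and
amplitude jitter (log-normal, 10% / 8%) provides within-class variability.
Spectra are the compound maps times unit-amplitude Gaussian band profiles
(σ = 10/14/12 cm⁻¹), plus a quadratic baseline, additive Gaussian noise
(sd 0.02) and Poisson-count cosmic spikes (rate 1e−6 per pixel-channel,
amplitude 10–50).  Child seeds derive from (master seed, cell index), so
any cell regenerates in isolation and every downstream number is a
deterministic function of the master seed.

Two dials support calibration experiments: `pattern_separation` linearly
interpolates all class spatial parameters toward their common mean (0 =
identically distributed classes, the null), and per-class `amp_scale`
introduces overall spectral differences when wanted.

Deliberate simplifications, hence limits on what passing tests show about
real data: Gaussian (not Lorentzian/Voigt) line shapes, additive Gaussian
(not shot) noise, a uniform wavenumber grid, no instrument PSF, no
autofluorescence photobleaching, and spatial patterns far simpler than
organelle biology.  The benchmark validates the *machinery* — feature
contracts, selector calibration, classifier correctness, the relative
ordering of the three approaches under a planted regime — not absolute
accuracies on any real cell line.

## Simulation studies and problem sizes

The standing studies in `ramancharm.studies` run 20 seeded replicates at a
reduced scale chosen so a full study completes in minutes on one core: an
80 px field, 320-point spectra and 10 cells per class for the accuracy
study (granule/droplet densities preserved by the scaling; below ~64 px the
texture statistics become too noisy for the planted separation to survive),
and a 48 px field, 256-point spectra, 6 cells per class, single channel for
the null calibration.  The default 120 px / 1024-point / 72-cell cohort is what the
structural checks generate.  Replicate seeds derive deterministically from
one master seed.

In the null study the Kolmogorov–Smirnov comparison is made per replicate
between the observed Fisher scores and scores recomputed under label
permutations of the same table, and the p-value is calibrated by
permutation: descriptor columns are strongly correlated, so the nominal
two-sample KS null (independent observations) is severely anticonservative
— it reports p ≈ 1e−12 on data that are null by construction.  The rank of
the observed leave-one-out KS distance among 99 permuted ones is exact
under label exchangeability whatever the correlation structure; the median
calibrated p over replicates is reported.

## Known limitations

- The descriptor bank follows the generic texture/statistics/polynomial
  recipe but is an independent implementation; individual feature values
  are not numerically interchangeable with any other implementation, only
  the contract (count, determinism, invariances) is.
- With ~18 training cells and thousands of features, PCA test-score
  shrinkage is material; the significance gate and covariance shrinkage
  mitigate but do not remove it.  Expect optimistic training metrics at
  this scale — the studies therefore only ever score held-out cells.
- ALS baseline correction solves one sparse system per pixel and is slow on
  full cubes; modpoly is vectorized across pixels.
- The segmentation is a single-threshold component labeling; touching cells
  are returned as one component.
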