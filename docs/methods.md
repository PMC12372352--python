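# Methods

## Scope and data model

`diffprint` analyzes planar single-particle tracks: ordered positions
(µm) at a fixed frame interval `dt` (default 1 s, matching 1 Hz
video acquisition), typically ~100 frames long. Positions are kept in
micrometers internally; microrheology converts to SI. Pixel-to-µm
calibration is the caller's responsibility (`length_unit` in the
reader), since it is instrument-specific. Frame gaps are rejected by
default (`allow_gaps=True` treats frames as contiguous instead — use
with care, as it silently compresses time).

## Time-averaged MSD and the power-law fit

For lag `n·dt` the time-averaged MSD is the mean of `|r_{i+n} − r_i|²`
over all start frames; the quartic moment is accumulated alongside for
the Gaussianity feature. Lags run to `floor(N/4)` by default (25 s for
N = 100): longer lags average very few displacement pairs and would
dominate the fit with noise. `D` and `α` come from ordinary least
squares on `(log τ, log MSD)`; zero-MSD lags are excluded, and fewer
than three positive lags marks the fit degenerate (immobile particle
without localization noise). Goodness of fit is the upper-tail
probability of `Σ (MSD_obs − MSD_fit)²/MSD_fit` against χ² with
`n_lags − 2` degrees of freedom, evaluated in linear MSD space. No
per-lag uncertainty weighting is applied; the fit range is configurable.

## Classical features

* **Fractal dimension** uses the Katz–George estimator
  `Df = log n / (log n + log(d_max/L))`: exactly 1 for straight
  equal-step paths and empirically ≈ 1.75 ± 0.17 (mean ± sd) for
  100-step planar Brownian walks — the estimator carries a finite-length
  bias below its asymptotic value of 2, which is why ensemble
  comparisons use a ±0.3 band around 2.
* **Trappedness** is the empirical confinement probability
  `1 − exp(0.2048 − 0.25117 · D_short t / r0²)` (clamped to [0, 1]),
  with `D_short` from a through-origin fit of the first two MSD lags and
  `r0` half the maximal extent. The two constants are the standard
  values of the trajectory-fingerprinting literature.
* **Gaussianity** is the mean over fitted lags of
  `⟨r⁴⟩/(2⟨r²⟩²) − 1`, zero for planar Gaussian displacements and
  bounded below by −0.5.
* **Kurtosis** projects steps onto the dominant eigenvector of the step
  covariance and reports Pearson kurtosis (normal = 3). Computing it on
  steps rather than positions makes it a property of the increment
  process, not of the net drift.

Degenerate inputs yield NaN; a row with any NaN feature is flagged and
excluded from machine learning by default.

## Hidden-Markov state features

A K-state (default 4) Gaussian HMM is fitted by EM to the 1-D
step-length sequence, with `n_restarts` (default 3) seeded
initializations and the best log-likelihood kept; states are relabeled
ascending by emission mean (ties by variance) so occupancies are
comparable across trajectories. Features are the Viterbi-path occupancy
fractions T0–T3 plus the mean run length ("dwell time") of the decoded
path. Caveat: on single-regime data an unconstrained Gaussian HMM tiles
the skewed (Rayleigh-like) step-length distribution with several
rapidly-alternating states; occupancy concentration alone therefore does
not indicate true switching. The discriminating statistics are the
spread of emission means and the dwell time, and the recovery tests are
phrased in those terms. K and the feature subset are configurable.

## Microrheology

The generalized Stokes–Einstein relation maps the tracer MSD to medium
viscoelasticity. Creep compliance is evaluated on the measured MSD per
lag; the complex modulus is evaluated from the *global* power-law fit at
`t₀ = 1/s₀` over a 60-point log-spaced grid `s₀ ∈ [0.01, 100] s⁻¹` —
the global fit doubles as the extrapolation to sub-frame times that the
`s₀ > 1/dt` half of the grid requires (measured lags start at `dt`). A
per-frequency local-slope `α(t₀)` variant was considered and not
implemented; the global exponent is the package's definition of `α`
throughout. The split into `G′`/`G″` uses `cos/sin(πα/2)` with `α`
clamped to `[10⁻³, 2]`: the lower clamp keeps Γ and the trigonometric
factors on their physical branch for immobile particles whose fitted `α`
is slightly negative; for `α > 1` the cosine factor makes `G′` negative
by construction, which downstream summaries treat as "negligible elastic
response". Viscosity averages `G″/ω` over the lowest frequency decade
(0.01–0.1 s⁻¹), the package's reading of "low-frequency limit". Feature
values are the means over the respective grids. All five features are
NaN for degenerate fits.

## Synthetic studies

The simulator emulates the acquisition the analysis expects: 100-frame,
1 Hz planar tracks of 100/200/1000 nm particles in three media
(PNCM, PACM-HEC, PACM-PAA) × two surface charges, with i.i.d. Gaussian
localization noise (default 0.02 µm, a typical localization precision)
added to true positions. Per-axis Brownian increments have variance
`2 D dt`; fractional Gaussian noise is generated exactly by
Davies–Harte circulant embedding (approximate synthesis would bias `α`
recovery); confined motion reflects radially at a circular boundary;
switching draws per-step states from a Markov chain and reports them as
ground truth. Across sizes, component diffusivities scale as 1/radius
(Stokes–Einstein). Study cells draw per-trajectory diffusivities from a
lognormal around the component value (`D_sigma`, default 0.3 log-units
in the heterogeneous design) to model the continuous spread of local
environments a heterogeneous hydrogel presents.

Three canned designs set the benchmark conditions: `disjoint`
(one Brownian population per medium, D = 0.001/0.1/10 µm²/s — trivially
separable, classifier ceiling), `identical` (all media alike —
classifier chance floor), and `heterogeneous` (the default study:
mostly immobile/subdiffusive mixtures whose weights differ per medium,
with a bimodal mobile population in PACM-HEC flanking PNCM's unimodal
one). The heterogeneous design is deliberately *nonlinearly* separable:
class identity lives in mixture weights and multimodality rather than in
a single threshold, which is why tree ensembles outperform linear and
instance-based members of the panel on it (F1 ≈ 0.7 at 100 trajectories
per medium). What passing these benchmarks does **not** show: the
simulator has no photophysics, no 3-D motion, no particle–matrix
interactions, and its class signal is constructed — real-data accuracy
depends on the actual media contrast.

## Classification and attribution

The panel holds seven classifiers with library-default hyperparameters
(recorded implicitly by the pinned sklearn version): SVM-RBF, kNN,
histogram gradient boosting, decision tree, logistic regression, random
forest, Fisher's LDA. Splits are stratified (70/30 holdout or 5-fold
CV); metrics are accuracy and macro precision/recall/F1; confusion
matrices aggregate over folds and are row-normalized for per-class
recall. Features are z-scored inside each training fold by default to
avoid leakage; a `global` mode standardizes before splitting for
workflows that scale once up front. Everything is deterministic given
(table, protocol, seed).

Per-class feature importance for the gradient-boosting model is
computed as Shapley values of `predict_proba`, estimated by Monte-Carlo
permutation sampling against a background sample (features switched one
at a time from a background draw to the explained row along random
orderings; 20 permutations × 100 explained rows by default). Mean
absolute attributions per feature and class are reported with the top-5
ranking by cross-class total. Sampling noise at the default budget is
well below the gap between informative and noise features in the test
designs; increase `n_permutations` for finer contrasts.

## Similarity analysis

Per feature and medium pair: area overlap integrates the pointwise
minimum of Scott-bandwidth Gaussian KDEs on a shared 512-point grid
padded by three pooled bandwidths; KL divergence (symmetrized/Jeffreys
by default so pairs are order-free; a flag restores one-directional),
cosine similarity and Euclidean distance operate on 50-bin shared-range
probability histograms with 10⁻¹⁰ smoothing for the logarithms.
Aggregation averages each metric over features per pair; the
overlap-difference ranking
`Δ(f) = overlap(PNCM, HEC) − overlap(PNCM, PAA)` surfaces the features
that drive one artificial medium's resemblance to the native reference.
Self-pairs are available as internal controls (overlap 1, KL 0, cosine
1, distance 0 up to grid error). Bandwidth rule and bin count are
configurable and recorded in the defaults above.

## Numerical/benchmark choices

Benchmark problem sizes were chosen to pin the statistics well inside
their tolerance bands at interactive runtimes: 500 trajectories for the
Newtonian closed loop (median recovered η within 20 % of truth), 300 per
Hurst value for `α = 2H` recovery (±0.1), 1000 for the Brownian
fractal-dimension ensemble (±0.3), 40 for HMM occupancy recovery
(±0.1). Random seeds appear explicitly in every simulation, HMM fit,
split, embedding and attribution; identical seeds give bit-identical
results.

## Known limitations

* No drift correction; directed motion contaminates `α` upward.
* The χ² p-value is a heuristic fit-quality score (no error model per
  lag), useful as a feature, not as a calibrated test.
* Microrheology assumes the generalized Stokes–Einstein relation holds
  locally — it does not for actively driven or strongly interacting
  tracers, and the sub-frame half of the modulus grid is model
  extrapolation.
* Gap handling, 3-D tracks and per-frequency local exponents are out of
  scope; types accept `d = 3` but the analysis path is validated for
  planar data only.
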