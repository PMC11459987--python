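# Methods

`petdeconv` treats post-reconstruction PET image analysis as a Bayesian
inverse problem.  The unknown is the in-situ activity concentration image
Φ (kBq/ml) on a model grid; the data is a single reconstructed PET image
Φ_obs on the scanner's pixel grid.  The posterior is sampled, not
optimized: the output is an ensemble of activity images, and every
quantitative result (lesion probability, region area, region activity,
credible intervals) is a statistic of that ensemble.

## Forward model

The scanner and reconstruction chain are modelled as a linear smoothing
operator G with a Gaussian averaging kernel,

    G_ij ∝ exp(−h_ij² / a²),

where h_ij is the physical distance (mm) between pixel centers and `a` is
the kernel range.  Every row of G is normalized to sum to one; border rows
are renormalized over in-image pixels only, so a constant image maps to
itself and no out-of-image data is invented.  The kernel is truncated at
4a (relative weights below exp(−16) ≈ 1e-7) to keep stencils small.  The
FWHM of the kernel is 2a√(ln 2).

When the model grid refines the data grid by an integer factor f, the
operator convolves on the fine grid (distances in mm) and then
block-averages f×f fine pixels into each data pixel.  Refinement is
strictly integer subdivision: a 4× refinement of 2.08 mm pixels gives
0.52 mm pixels (stated "quarter pixel sizes" that are not exact quarters
are treated as rounded descriptions).  Aggregation is the arithmetic mean,
so activity-concentration units are preserved.

`a` is calibrated on a scan of a known object by grid search: the squared
log-residual ‖log Φ_obs − log GΦ_ref‖² is evaluated for a from 0 to 10 mm
in 0.1 mm steps and the minimizer taken (ties go to the smaller a — the
least-smoothing explanation).  The recovery is exact on the grid when the
observation is noise-free; under the calibrated noise level the estimate
scatters by roughly ±0.3 mm on a 64×64 phantom.

## Noise model

Iterative (OSEM-type) reconstructions produce correlated, signal-dependent,
approximately log-normal noise.  The model is a Gaussian field in the
log10 image domain with covariance

    Ct = D^{1/2} R D^{1/2},
    R = (1 − η) exp(−h²/r²) + η I,

with h in data-grid pixel units.  D holds per-pixel log10 variances: the
marginal std is anchored at two measured levels — std(log10 Φ_obs) =
0.1060 at 0.43 kBq/ml and 0.0402 at 2.77 kBq/ml — and linearly
interpolated in the local activity level, clamped to the end values
outside the anchor span (the low clamp reflects that low-count regions are
not better determined; the high clamp is the symmetric conservative
choice).  The local level is a 4×4 moving average of the observed image
(edge-truncated windows), which linearizes the signal dependence so Ct is
built and Cholesky-factorized exactly once.  To avoid overfitting with
this frozen linearization, the variance is inflated by 20%.

The nugget η (default 0.05) is a micro-scale white-noise component.  It is
needed because the pure Gaussian-type correlation model is analytically
smooth and its precision matrix amplifies rough residual components
essentially without bound: without a nugget, the log-likelihood differences
between images become dominated by near-null directions of Ct and the
sampler can "explain" large structured residuals at negligible cost while
being absurdly sensitive to others.  A 5% nugget bounds the spectrum,
leaves the fitted semivariogram essentially unchanged, and matches the
common geostatistical practice of never fitting a nugget-free Gaussian
model to data.

The correlation range r is estimated by classical semivariogram analysis
of log10 residuals in a homogeneous region: the experimental semivariogram
is binned to unit-pixel isotropic lags and the Gaussian model
γ(h) = σ²(1 − exp(−h²/r²)) fitted by least squares weighted with per-lag
pair counts.  (Lag binning and weighting are not uniquely standard; these
are this package's choices, frozen for reproducibility.)

## Likelihood

With a candidate image Φ, the log-normal likelihood evaluates the
prediction GΦ against the observation:

    log L(Φ) = const − ½ (log10 GΦ − log10 Φ_obs)ᵀ Ct⁻¹ (log10 GΦ − log10 Φ_obs) [− Σ ln (GΦ)_i].

The bracketed Jacobian term appears if the log-normal density over the
*linear* activity variable is followed literally with its normalization
evaluated at the prediction; because the prediction varies along the
chain, the term acts on the Metropolis ratio as a strong downward pull on
activity (≈ N nats per e-fold of intensity for N pixels).  Both readings
are implemented (`include_jacobian=True/False`).  The default of the
low-level `Likelihood` class is the literal reading; the end-to-end
phantom study in the test-suite uses the "Gaussian in log space" reading
(`include_jacobian=False`), which is consistent with how the noise
magnitudes were calibrated (as stds of log residuals) and does not bias
the recovered activity.  A multivariate Gaussian likelihood in the linear
domain (for FBP-type reconstructions) is available under `kind="gaussian"`.

Quadratic forms are computed by triangular solves against the cached
Cholesky factor; a dense-inverse evaluation is used as the test oracle.

## Priors

Both priors ride on a stationary zero-mean unit-variance Gaussian random
field (GRF) with Gaussian-type correlation exp(−h²/r²), simulated by
circulant embedding on a torus padded by 4r: the spectrum is the FFT of the
wrapped covariance, tiny negative eigenvalues are clipped, and the field is
rescaled so the pixel marginal is exactly N(0, 1).

* **Truncated bimodal (lesion/background) prior**: latent range 10 px;
  pixels whose latent value falls below the 9% normal quantile (−1.3408;
  the rounded −1.34 can be passed explicitly) are high-activity.  The two
  region levels are scalars drawn uniformly from [0.1, 1.1] and
  [2.1, 3.2] kBq/ml and random-walked within their intervals along the
  chain (reflected walk, scale 0.04 of the interval width, proposed with
  probability 0.2 per move).  The level-walk scale is deliberately *not*
  tied to the latent exploration step: the two scalars need small moves to
  mix regardless of how the field moves, and coupling them to an adapted
  step freezes the levels near their initial draws.
* **Trimodal tissue prior**: latent range 8 px, normal-score transformed
  through the quantile function of a three-component marginal: lesion
  N(2.7, 0.13²), soft tissue N(0.55, 0.15²), lung-like U(0.06, 0.2)
  kBq/ml.  The mixture weights are a modelling choice (no canonical
  values exist); the default (0.10, 0.45, 0.45) makes lesion tissue rare.
  The quantile table is truncated to activities ≥ 1e-3 kBq/ml because the
  soft-tissue component carries ~1e-4 probability mass below zero, which a
  positive activity image cannot represent.

## Sampler

The extended Metropolis algorithm needs only (i) a prior that can be
*sampled* by a random walk and (ii) likelihood ratios — the prior density
is never evaluated.  Each iteration proposes a prior-preserving
perturbation and accepts with probability min(1, L'/L), decided in log
space; proposal and acceptance randomness come from separate RNG streams
spawned from one seed, so runs are bitwise reproducible.

States store the *white* field underlying the GRF.  The exploration kernel
mixes two exactly prior-preserving moves:

* global gradual deformation w′ = √(1−ε²) w + ε v with a fresh white field
  v and ε = step (probability `p_global`, default 0.4; a step of 1 is an
  independent prior draw);
* local block resimulation: a random rectangular block of the white field
  (side 1–16, toroidal wrap) is redrawn — completely for small blocks
  (side ≤ 4; these "nucleation" moves introduce or delete one
  lesion-scale feature), partially (coefficient min(1, 8·step)) for large
  ones.  Because white components are i.i.d., redrawing a subset is an
  exact conditional resimulation of the prior — the sequential-Gibbs
  mechanism — and it perturbs the colored field only within the block plus
  one correlation length.

The local moves are what make the posterior reachable in practice: they
let the chain edit one lesion-scale feature at a time, whereas pure global
deformation at an acceptable acceptance rate mixes at a rate that
collapses with the pixel count (on the 64×64 study, a global-only kernel
never finds three of the four lesions within 5×10⁴ iterations).  A dense
conditional block-resimulation in the colored domain is included as a
small-grid fidelity oracle for the same mechanism.

Step-size adaptation (multiplicative, toward a target acceptance rate of
0.30) runs only during an initial window and is frozen afterwards so the
post-adaptation kernel is a fixed, valid MCMC kernel.  Note that small
block moves that do not flip any truncation threshold leave the likelihood
unchanged and are always accepted, so the raw acceptance rate overstates
movement for the bimodal prior; the defaults (fixed step 0.15,
p_global 0.4, p_level 0.2 for the phantom study) were chosen by comparing
integrated autocorrelation times, not acceptance alone — adaptation is
best switched off for this prior.

Burn-in is detected from the log-likelihood trace: the stationary band is
the 5–95% interval of the final half, and burn-in is the first iteration
inside the band from which at least 85% of the remaining trace stays
inside.  A trace that trends monotonically through its whole final half is
declared never-stabilized (chain length returned, with a warning).  The
thinning interval is ceil(2τ), with τ the integrated autocorrelation time
of the post-burn-in trace (Geyer initial-positive-sequence estimator);
full states are stored every 10 iterations and the ensemble takes stored
states at least one thinning interval apart.

## Posterior analysis

From the ensemble: pointwise mean and unbiased variance maps; exceedance
maps P(Φ > t) with the strict inequality and default t = 1.5 kBq/ml (the
natural split between the low- and high-activity modes of both priors);
and connected-region posteriors: per realization, the image is
thresholded and the connected component containing a seed pixel measured
(4-neighbour connectivity by default, 8-neighbour available).  A
realization whose seed pixel is below threshold counts as a non-detection
(area 0); region-activity quantiles are computed over detected
realizations only, while the detection probability counts all.  Quantiles
use the linear-interpolation convention (numpy's default), fixed so tables
are reproducible bit-for-bit.

## Synthetic phantom study

The generator mimics a NEMA-like body phantom slice: constant background
0.43 kBq/ml, hot circles at 2.77 kBq/ml, graded radii whose default
data-grid areas are near a NEMA central-slice series, pixel size 2.08 mm.
Pixels are labelled by center containment so true areas are exact integer
pixel counts.  Observations are simulated by applying the calibrated
operator and one draw of the noise model.  The generator simulates with
the anchored noise level (inflation 1) — the 20% inflation is an analysis
safeguard, not a data property — while the analysis pipeline keeps its
default inflation.

The end-to-end study in the test suite uses a 64×64 grid (scaled down from
the 90×90 slice for run-time), four circles with areas of roughly 6–60
data pixels, a true kernel range of 3.0 mm, noise correlation range 2.0 px,
5×10⁴ iterations, and the bimodal prior.  Typical outcomes: the true area
falls inside the equal-tailed 95% credible interval for at least 3 of 4
circles, and the posterior median region activity stays near the true
2.77 kBq/ml while the raw observed image underestimates the smallest
circle's activity by tens of percent (the partial-volume effect the method
is designed to undo).

What this does and does not show: the generator draws data exactly from
the assumed forward and noise models, so these tests validate the
machinery (calibration recovery, posterior computation, coverage under a
well-specified model), not robustness to model misspecification,
spatially varying PSF, non-stationary noise magnitude, or real scanner
physics — all of which remain open for phantoms measured on hardware.

## Numerical choices and degenerate inputs

* Covariance factorization adds escalating diagonal jitter
  (1e-10…1e-4 of the mean diagonal) only if Cholesky fails; a
  zero-variance model short-circuits to exact means.
* Semivariogram estimation enumerates integer pixel offsets (vectorized),
  so masked 128×128 fields stay fast; bins with no pairs are dropped.
* The kernel-width grid search breaks ties toward smaller a.
* Likelihood domain errors (non-positive predictions) reject the proposal
  rather than aborting the chain.
* Images must be strictly positive wherever logs are taken; violations
  raise a `DomainError` naming the pixel.

## Known limitations

2D slices only (volumes are processed slice-wise); a single stationary
isotropic PSF; noise magnitude anchored at just two levels; the ρ2 mixture
weights and the sampler's kernel mixture proportions are modelling choices;
credible intervals from short chains (tens of effective realizations) are
themselves noisy — the chain length, not the method, limits their
precision.

Two biases of the frozen linearized noise model are worth knowing.  First,
the per-pixel variance is evaluated at a smoothed version of the *noisy*
observation, so the quadratic-form weights are anticorrelated with the
local noise: pixels the noise pushed high get smaller stds and more
weight.  On the 64×64 study this shows up as a modest upward pull
(≈ +0.1–0.3 kBq/ml) on the recovered high-region activity — it is a
property of the likelihood given the data, not of the sampler, and it
shrinks as regions grow (the smoothing window averages more noise away).
Second, with only tens of effective posterior draws the equal-tailed 95%
interval is estimated from few order statistics and its frequentist
coverage over repeated datasets is below nominal; longer chains widen and
stabilize it.
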