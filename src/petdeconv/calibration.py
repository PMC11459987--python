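"""Calibration of the smoothing kernel and of the correlated log-normal noise model.

Both are estimated once from a scan of a known object (a phantom):

* the kernel range ``a`` minimizes the squared log-data residual
  ``|| log(obs) - log(G(a) @ ref) ||^2`` over a grid of candidate values;
* the noise is a stationary, isotropic, Gaussian-correlated field in the
  log10 image domain, with a signal-dependent marginal standard deviation
  anchored at two activity levels and linearly interpolated between them.

The per-pixel noise level is linearized by evaluating the anchored std at a
4x4 moving average of the observed image, and the resulting variance is
inflated by 20% so the frozen (linearized) model does not understate the
noise.  The full covariance ``Ct = D^1/2 R D^1/2`` is assembled and
factorized once; likelihood evaluations reuse the factorization.

All log-domain quantities are in base 10, matching how anchored noise
standard deviations are conventionally reported; the Metropolis ratio is
invariant to the base up to the documented Jacobian convention (see
``petdeconv.likelihood``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage, optimize

from .grids import ActivityImage, BinaryMask, DomainError, ImageGrid, ReconstructedPET
from .psf import ConvolutionOperator, build_operator

logger = logging.getLogger(__name__)

#: std(log10(obs)) measured at a low and a high activity level (kBq/ml)
DEFAULT_ANCHORS = ((0.43, 0.1060), (2.77, 0.0402))


# ---------------------------------------------------------------------------
# Kernel-width estimation
# ---------------------------------------------------------------------------

def log_residual(
    obs: ReconstructedPET, ref: ActivityImage, op: ConvolutionOperator
) -> tuple[np.ndarray, float]:
    """Log-data residual ``n = log(obs) - log(G ref)`` and its squared norm.

    Natural logarithms; the norm is the quantity minimized by the kernel
    width search (the base only rescales the curve, not its argmin).
    """
    pred = op.apply(ref).values
    if np.any(obs.values <= 0) or np.any(pred <= 0):
        raise DomainError("log residual requires strictly positive images")
    resid = np.log(obs.values) - np.log(pred)
    return resid, float(np.sum(resid**2))


@dataclass
class KernelWidthFit:
    a_mm: float
    a_grid: np.ndarray
    residual_norms: np.ndarray


def estimate_kernel_width(
    obs: ReconstructedPET,
    ref: ActivityImage,
    a_min: float = 0.0,
    a_max: float = 10.0,
    a_step: float = 0.1,
    support_radius_in_a: float = 4.0,
) -> KernelWidthFit:
    """Grid search for the kernel range minimizing the log-data residual norm.

    Ties are broken toward the smaller ``a`` (the least-smoothing explanation).
    """
    if a_min > a_max:
        raise ValueError("a_min must be <= a_max")
    if a_step <= 0:
        raise ValueError("a_step must be > 0")
    n_steps = int(np.floor((a_max - a_min) / a_step + 1e-9)) + 1
    a_grid = a_min + a_step * np.arange(n_steps)
    if a_grid.size == 0:
        raise ValueError("empty kernel-width grid")
    norms = np.empty(a_grid.size)
    for k, a in enumerate(a_grid):
        op = build_operator(a, ref.grid, obs.grid, support_radius_in_a)
        _, norms[k] = log_residual(obs, ref, op)
    best = int(np.argmin(norms))  # argmin returns the first (smallest a) on ties
    return KernelWidthFit(float(a_grid[best]), a_grid, norms)


# ---------------------------------------------------------------------------
# Semivariogram estimation and covariance fitting
# ---------------------------------------------------------------------------

@dataclass
class SemivariogramEstimate:
    """Isotropic experimental semivariogram, binned to unit-pixel lags."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray


def empirical_semivariogram(
    field: np.ndarray, mask: np.ndarray | BinaryMask | None = None, max_lag: int = 10
) -> SemivariogramEstimate:
    """Experimental semivariogram gamma(h) = mean of 0.5 (x_i - x_j)^2 over
    pixel pairs at Euclidean distance h, binned to unit-pixel bins centered
    on integer lags.

    Pairs are enumerated by integer pixel offsets, so large masked grids stay
    cheap (one vectorized pass per offset).
    """
    field = np.asarray(field, dtype=float)
    if isinstance(mask, BinaryMask):
        mask = mask.values
    if mask is None:
        mask = np.ones(field.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must select at least 2 pixels")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")

    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    n, m = field.shape
    for di in range(0, max_lag + 1):
        for dj in range(-max_lag, max_lag + 1):
            if di == 0 and dj <= 0:
                continue  # each unordered pair once
            h = np.hypot(di, dj)
            b = int(round(h))
            if b > max_lag:
                continue
            i0, i1 = (0, n - di)
            j0, j1 = (max(0, -dj), min(m, m - dj))
            if i1 <= i0 or j1 <= j0:
                continue
            a = field[i0:i1, j0:j1]
            bfield = field[i0 + di : i1 + di, j0 + dj : j1 + dj]
            valid = mask[i0:i1, j0:j1] & mask[i0 + di : i1 + di, j0 + dj : j1 + dj]
            d2 = (a[valid] - bfield[valid]) ** 2
            sums[b] += 0.5 * d2.sum()
            counts[b] += d2.size
    keep = counts > 0
    keep[0] = False  # lag 0 carries no information
    if not keep.any():
        raise ValueError("no usable pixel pairs in any lag bin")
    lags = np.arange(max_lag + 1, dtype=float)[keep]
    return SemivariogramEstimate(lags, sums[keep] / counts[keep], counts[keep])


def gaussian_semivariogram(h, r, sill):
    """Gaussian-type semivariogram model ``sill * (1 - exp(-h^2/r^2))``."""
    h = np.asarray(h, dtype=float)
    if r == 0:
        return np.where(h > 0, sill, 0.0)
    return sill * (1.0 - np.exp(-(h**2) / r**2))


def fit_gaussian_covariance(sv: SemivariogramEstimate) -> tuple[float, float]:
    """Weighted least-squares fit of the Gaussian semivariogram model.

    Returns ``(range_px, sill)``.  Weights are the per-lag pair counts.
    """
    if sv.lags.size < 3:
        raise ValueError("need at least 3 lag bins to fit range and sill")
    sill0 = float(np.max(sv.gamma))
    if sill0 <= 0:
        raise ValueError("semivariogram is identically zero; cannot fit a range")
    # initial range: first lag reaching ~63% of the apparent sill
    above = sv.lags[sv.gamma >= (1 - np.exp(-1.0)) * sill0]
    r0 = float(above[0]) if above.size else float(sv.lags[-1])
    try:
        popt, _ = optimize.curve_fit(
            gaussian_semivariogram,
            sv.lags,
            sv.gamma,
            p0=[max(r0, 0.5), sill0],
            sigma=1.0 / np.sqrt(sv.counts),
            bounds=([1e-6, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - scipy non-convergence
        raise RuntimeError(f"Gaussian covariance fit did not converge: {err}") from err
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Level-dependent noise magnitude
# ---------------------------------------------------------------------------

def estimate_level_stds(
    obs: ReconstructedPET, masks: list[BinaryMask]
) -> list[tuple[float, float]]:
    """Per region: (sample mean activity, sample std of log10 values)."""
    out = []
    for mask in masks:
        vals = obs.values[mask.values]
        if vals.size < 2:
            raise ValueError("each mask must select at least 2 pixels")
        if np.any(vals <= 0):
            raise DomainError("log10 requires strictly positive values")
        std = float(np.std(np.log10(vals), ddof=1))
        if std < 1e-12:
            warnings.warn("degenerate region: std of log10 values is (numerically) 0")
        out.append((float(vals.mean()), std))
    return out


def _interp_std(anchors, activity):
    levels = np.array([a[0] for a in anchors], dtype=float)
    stds = np.array([a[1] for a in anchors], dtype=float)
    if np.any(np.diff(levels) <= 0):
        raise ValueError("anchor activities must be strictly increasing")
    if np.any(stds <= 0):
        raise ValueError("anchor stds must be > 0")
    # np.interp clamps to the end values outside the anchor span
    return np.interp(activity, levels, stds)


# ---------------------------------------------------------------------------
# The linearized noise model
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Correlated, signal-dependent noise in the (log10 or natural) image domain.

    ``Ct = D^1/2 R D^1/2`` where ``R_ij = exp(-h_ij^2 / r^2)`` (h in data-grid
    pixel units) and ``D`` holds per-pixel variances obtained by interpolating
    the anchored stds at the smoothed local signal level and inflating by
    ``inflation``.

    ``domain='log10'`` means the covariance describes ``log10`` residuals
    (the log-normal noise model); ``domain='natural'`` describes residuals in
    activity units (the Gaussian noise model).
    """

    grid: ImageGrid
    anchors: tuple = DEFAULT_ANCHORS
    range_px: float = 1.85
    inflation: float = 1.20
    window: int = 4
    domain: str = "log10"
    nugget: float = 0.05
    level_map: np.ndarray | None = None
    std_map: np.ndarray = field(init=False, repr=False)
    _chol: np.ndarray = field(init=False, repr=False, default=None)
    _logdet: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self):
        if self.range_px < 0:
            raise ValueError("correlation range must be >= 0")
        if self.domain not in ("log10", "natural"):
            raise ValueError("domain must be 'log10' or 'natural'")
        if self.level_map is None:
            raise ValueError("level_map is required (use build_noise_model)")
        self.level_map = np.asarray(self.level_map, dtype=float)
        if self.level_map.shape != self.grid.shape:
            raise ValueError("level map shape does not match grid")
        # inflation multiplies the variance
        self.std_map = _interp_std(self.anchors, self.level_map) * np.sqrt(self.inflation)

    def std_at_level(self, activity) -> np.ndarray | float:
        """Anchored std (without inflation) at the given activity level(s);
        piecewise linear in activity, clamped outside the anchor span."""
        out = _interp_std(self.anchors, np.asarray(activity, dtype=float))
        return float(out) if np.isscalar(activity) else out

    # -- covariance assembly ------------------------------------------------

    def correlation_matrix(self) -> np.ndarray:
        """Stationary correlation matrix R over all grid pixels.

        Gaussian-type correlation with a small nugget (micro-scale white
        component): ``R = (1 - nugget) exp(-h^2/r^2) + nugget I``.  The
        nugget keeps the precision matrix well conditioned — the pure
        Gaussian model is analytically smooth and its inverse amplifies
        rough residual components without bound.
        """
        n, m = self.grid.shape
        if self.range_px == 0:
            return np.eye(n * m)
        ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
        ri = ii.ravel().astype(float)
        ci = jj.ravel().astype(float)
        d2 = np.subtract.outer(ri, ri) ** 2
        d2 += np.subtract.outer(ci, ci) ** 2
        R = (1.0 - self.nugget) * np.exp(-d2 / self.range_px**2)
        R[np.diag_indices_from(R)] += self.nugget
        return R

    def covariance(self) -> np.ndarray:
        """Dense ``Ct`` (row-major pixel ordering)."""
        s = self.std_map.ravel()
        return self.correlation_matrix() * np.outer(s, s)

    def _factorize(self):
        if self._chol is not None:
            return
        C = self.covariance()
        scale = float(np.mean(np.diag(C)))
        if scale == 0.0:  # degenerate zero-variance model
            self._chol = np.zeros_like(C)
            self._logdet = -np.inf
            return
        for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
            try:
                self._chol = np.linalg.cholesky(C + jitter * scale * np.eye(C.shape[0]))
                if jitter:
                    logger.warning("noise covariance needed diagonal jitter %.0e", jitter)
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover
            raise np.linalg.LinAlgError("noise covariance could not be factorized")
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def cholesky(self) -> np.ndarray:
        self._factorize()
        return self._chol

    @property
    def logdet(self) -> float:
        self._factorize()
        return self._logdet

    def whiten(self, residual_flat: np.ndarray) -> np.ndarray:
        """Solve ``L y = residual`` so that ``|y|^2 = r^T Ct^-1 r``."""
        self._factorize()
        return linalg.solve_triangular(
            self._chol, residual_flat, lower=True, check_finite=False
        )

    # -- simulation ---------------------------------------------------------

    def simulate(self, mean_image: ReconstructedPET, rng) -> ReconstructedPET:
        """Draw one noisy realization around a noise-free mean image."""
        if mean_image.grid != self.grid:
            raise ValueError("mean image grid does not match the noise model grid")
        rng = np.random.default_rng(rng)
        self._factorize()
        z = (self._chol @ rng.standard_normal(self.grid.n_pixels)).reshape(self.grid.shape)
        if not z.any():  # degenerate zero-variance model: mean returned exactly
            return ReconstructedPET(self.grid, mean_image.values.copy(), role="observed")
        if self.domain == "log10":
            vals = 10.0 ** (np.log10(mean_image.values) + z)
        else:
            vals = mean_image.values + z
        return ReconstructedPET(self.grid, vals, role="observed")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Window x window moving average with edge-truncated windows."""
    values = np.asarray(values, dtype=float)
    num = ndimage.uniform_filter(values, size=window, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(values), size=window, mode="constant", cval=0.0)
    return num / den


def build_noise_model(
    obs: ReconstructedPET,
    anchors=DEFAULT_ANCHORS,
    range_px: float = 1.85,
    inflation: float = 1.20,
    window: int = 4,
    domain: str = "log10",
    nugget: float = 0.05,
) -> NoiseModel:
    """Linearized noise model: the local signal level is the ``window``-pixel
    moving average of the observed image, frozen for all later likelihood
    evaluations."""
    level = moving_average(obs.values, window) if window > 1 else obs.values.copy()
    return NoiseModel(
        grid=obs.grid,
        anchors=tuple(tuple(a) for a in anchors),
        range_px=range_px,
        inflation=inflation,
        window=window,
        domain=domain,
        nugget=nugget,
        level_map=level,
    )


def simulate_noise(nm: NoiseModel, mean_image: ReconstructedPET, seed=None) -> ReconstructedPET:
    """Functional wrapper around :meth:`NoiseModel.simulate`."""
    return nm.simulate(mean_image, np.random.default_rng(seed))
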