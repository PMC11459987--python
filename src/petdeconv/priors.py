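"""Explicit geostatistical prior models and prior-preserving perturbations.

Both priors are built on a stationary, zero-mean, unit-variance Gaussian
random field (GRF) with Gaussian-type correlation ``exp(-h^2/r^2)`` (h in
model-grid pixels).  The field is synthesized by circulant embedding: an
i.i.d. standard-normal "white" field on a padded torus is colored in the
frequency domain by the square root of the embedding eigenvalues.  Tiny
negative embedding eigenvalues are clipped and the spectrum rescaled so the
marginal is exactly N(0, 1).

Sampler states store the *white* field.  This makes two exactly
prior-preserving exploration moves available:

* global gradual deformation ``w' = sqrt(1-eps^2) w + eps v`` with ``v`` a
  fresh white field (the classic scheme; also how ``step=1`` yields an
  independent prior draw), and
* local block resimulation: a random rectangular block of the white field is
  (partially) redrawn.  Because the white components are i.i.d., this is an
  exact conditional resimulation of a subset of the prior — the
  sequential-Gibbs mechanism — and it perturbs the colored field only within
  the block plus one correlation length, which lets the chain edit one
  region of the image at a time.

The production kernel mixes the two (see :func:`perturb_white`); both leave
the prior invariant for any step, so iterating only the exploration step
samples the prior.

Two image-level priors are provided:

* :class:`TruncatedBimodalPrior` — a two-valued (lesion/background) image:
  the smallest ``high_fraction`` of the latent field is labelled
  high-activity, and each region is populated with one uniform draw from its
  activity interval.
* :class:`TrimodalTissuePrior` — a normal-score transform of the latent
  field through the quantile function of a three-component tissue mixture
  (lesion / soft tissue / lung-like), giving a continuous image with the
  prescribed marginal and the spatial correlation of the latent field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy.special import ndtr, ndtri
from scipy.stats import norm, uniform

from .grids import ActivityImage, ImageGrid


# ---------------------------------------------------------------------------
# Latent Gaussian random field
# ---------------------------------------------------------------------------

class GaussianRandomField:
    """Unit-variance stationary GRF with correlation ``exp(-h^2/r^2)``.

    ``sample_white`` draws the underlying i.i.d. field on the padded torus;
    ``color`` maps a white field to the correlated field on the grid.  With
    ``range_px == 0`` the torus equals the grid and ``color`` is the identity.
    """

    def __init__(self, grid: ImageGrid, range_px: float):
        if range_px < 0:
            raise ValueError("correlation range must be >= 0")
        self.grid = grid
        self.range_px = float(range_px)
        if self.range_px == 0:
            self.torus_shape = grid.shape
            self._sqrt_eig = None
            return
        pad = int(np.ceil(4.0 * self.range_px))
        ny = sfft.next_fast_len(grid.n_rows + pad)
        nx = sfft.next_fast_len(grid.n_cols + pad)
        self.torus_shape = (ny, nx)
        ky = np.minimum(np.arange(ny), ny - np.arange(ny))
        kx = np.minimum(np.arange(nx), nx - np.arange(nx))
        d2 = ky[:, None] ** 2 + kx[None, :] ** 2
        cov = np.exp(-d2 / self.range_px**2)
        eig = sfft.fft2(cov).real
        neg = eig < 0
        if neg.any():
            clipped = -eig[neg].sum() / eig.size
            if clipped > 1e-6:
                import warnings

                warnings.warn(
                    f"circulant embedding clipped eigenvalue mass {clipped:.2e}; "
                    "covariance is slightly approximated"
                )
            eig[neg] = 0.0
        # after clipping the stationary variance is mean(eig); rescale to 1
        # so the pixel marginal stays exactly standard normal
        self._sqrt_eig = np.sqrt(eig / eig.mean())

    def sample_white(self, rng) -> np.ndarray:
        return np.random.default_rng(rng).standard_normal(self.torus_shape)

    def color(self, white: np.ndarray) -> np.ndarray:
        """Correlated field on the grid from a white field on the torus."""
        if self._sqrt_eig is None:
            return white
        fld = sfft.ifft2(self._sqrt_eig * sfft.fft2(white)).real
        return fld[: self.grid.n_rows, : self.grid.n_cols]

    def sample(self, rng) -> np.ndarray:
        """One correlated realization; exactly N(0,1) marginally."""
        return self.color(self.sample_white(rng))


def simulate_latent(grid: ImageGrid, range_px: float, seed=None) -> np.ndarray:
    """Functional one-shot GRF draw (reproducible under ``seed``)."""
    return GaussianRandomField(grid, range_px).sample(np.random.default_rng(seed))


def perturb_latent(z: np.ndarray, w: np.ndarray, step: float) -> np.ndarray:
    """Gradual-deformation mixing; exactly preserves the Gaussian law.

    ``step`` in (0, 1]: 0+ leaves the field unchanged, 1 replaces it with the
    independent draw ``w``.
    """
    if not (0.0 < step <= 1.0):
        raise ValueError(f"step must be in (0, 1], got {step}")
    return np.sqrt(1.0 - step**2) * z + step * w


def perturb_white(
    white: np.ndarray,
    step: float,
    rng,
    p_global: float = 0.5,
    block_gain: float = 8.0,
    block_sides=(1, 2, 4, 8, 16),
) -> np.ndarray:
    """One prior-preserving exploration move on the white field.

    With probability ``p_global`` (or always when ``step == 1``) the whole
    field is mixed with a fresh draw at coefficient ``step``; otherwise a
    random block (side drawn from ``block_sides``, toroidal wrap) is mixed at
    the larger coefficient ``min(1, block_gain * step)`` — except that small
    blocks (side <= 4) are always redrawn completely: these are the
    "nucleation" moves that can introduce or delete one lesion-scale feature,
    and a partial mix of a few white components cannot.  All moves leave the
    i.i.d. N(0,1) law invariant for any step, and all shrink to the identity
    as ``step -> 0`` except the always-full small-block redraws, whose
    footprint (a handful of white components) is itself small.
    """
    if not (0.0 < step <= 1.0):
        raise ValueError(f"step must be in (0, 1], got {step}")
    rng = np.random.default_rng(rng)
    ny, nx = white.shape
    if step >= 1.0 or rng.random() < p_global:
        return perturb_latent(white, rng.standard_normal(white.shape), step)
    side = int(rng.choice(block_sides))
    gamma = 1.0 if side <= 4 else min(1.0, block_gain * step)
    i0 = int(rng.integers(ny))
    j0 = int(rng.integers(nx))
    ii = np.arange(i0, i0 + min(side, ny)) % ny
    jj = np.arange(j0, j0 + min(side, nx)) % nx
    out = white.copy()
    blk = out[np.ix_(ii, jj)]
    out[np.ix_(ii, jj)] = np.sqrt(1.0 - gamma**2) * blk + gamma * rng.standard_normal(blk.shape)
    return out


def block_conditional_resample(
    z: np.ndarray, grid: ImageGrid, range_px: float, block: tuple[slice, slice], rng
) -> np.ndarray:
    """Dense sequential-Gibbs move in the *colored* domain: redraw a
    rectangular block of the latent field from its exact Gaussian conditional
    given the remaining pixels.

    O(n_pixels^3) linear algebra; a fidelity oracle for small grids, not the
    production kernel.
    """
    rng = np.random.default_rng(rng)
    n, m = grid.shape
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    inblk = np.zeros((n, m), dtype=bool)
    inblk[block] = True
    pos = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    C = np.exp(-d2 / range_px**2) if range_px > 0 else np.eye(n * m)
    C += 1e-10 * np.eye(n * m)
    a = inblk.ravel()
    b = ~a
    Cab = C[np.ix_(a, b)]
    Cbb = C[np.ix_(b, b)]
    solve = np.linalg.solve(Cbb, np.column_stack([z.ravel()[b][:, None], Cab.T]))
    mu = Cab @ solve[:, 0]
    Cc = C[np.ix_(a, a)] - Cab @ solve[:, 1:]
    L = np.linalg.cholesky(Cc + 1e-10 * np.eye(Cc.shape[0]))
    znew = z.copy()
    znew[inblk] = mu + L @ rng.standard_normal(Cc.shape[0])
    return znew


# ---------------------------------------------------------------------------
# Prior base classes
# ---------------------------------------------------------------------------

class LatentGaussianPrior:
    """Common machinery: a latent GRF plus a transform to activity.

    Subclasses define the state layout, the activity transform, and the
    perturbation; all perturbations are prior-preserving so that iterating
    only the exploration step samples the prior.
    """

    def __init__(self, grid: ImageGrid, range_px: float,
                 p_global: float = 0.4, block_gain: float = 8.0):
        self.grid = grid
        self.range_px = float(range_px)
        self.grf = GaussianRandomField(grid, range_px)
        self.p_global = p_global
        self.block_gain = block_gain

    def _perturb_white(self, white, step, rng):
        return perturb_white(white, step, rng, self.p_global, self.block_gain)

    def initial(self, rng):
        raise NotImplementedError

    def perturb(self, state, step: float, rng):
        raise NotImplementedError

    def activity(self, state) -> ActivityImage:
        raise NotImplementedError

    def latent(self, state) -> np.ndarray:
        """The colored (correlated, unit-variance) latent field of a state."""
        raise NotImplementedError


class TransformedGaussianPrior(LatentGaussianPrior):
    """GRF prior with a monotone pointwise transform (state = white field)."""

    def __init__(self, grid: ImageGrid, range_px: float, transform=np.exp, **kw):
        super().__init__(grid, range_px, **kw)
        self.transform = transform

    def initial(self, rng):
        return self.grf.sample_white(rng)

    def perturb(self, state, step, rng):
        return self._perturb_white(state, step, rng)

    def activity(self, state) -> ActivityImage:
        return ActivityImage(self.grid, self.transform(self.grf.color(state)))

    def latent(self, state) -> np.ndarray:
        return self.grf.color(state)


# ---------------------------------------------------------------------------
# Truncated bimodal prior (phantom-style lesions on background)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rho1State:
    white: np.ndarray
    low: float
    high: float


class TruncatedBimodalPrior(LatentGaussianPrior):
    """Two-valued lesion/background prior via a truncated GRF.

    Pixels whose latent value falls below the ``high_fraction`` quantile of
    the standard normal are labelled high-activity; the two region levels are
    single uniform draws from ``low_interval`` and ``high_interval`` (kBq/ml).

    Parameters
    ----------
    high_fraction : float
        Expected fraction of high-activity pixels (default 0.09).
    threshold : float, optional
        Override the exact quantile ``ndtri(high_fraction)`` (e.g. the
        rounded -1.34 used in print).
    p_level : float
        Per-perturbation probability of also re-drawing one region level by a
        reflected random walk inside its interval.
    level_step : float
        Random-walk scale of a level move as a fraction of the interval
        width.  Fixed (not tied to the latent exploration step): the two
        scalar levels need small steps to mix regardless of how large the
        accepted field moves are.
    """

    def __init__(
        self,
        grid: ImageGrid,
        range_px: float = 10.0,
        high_fraction: float = 0.09,
        low_interval: tuple[float, float] = (0.1, 1.1),
        high_interval: tuple[float, float] = (2.1, 3.2),
        threshold: float | None = None,
        p_level: float = 0.2,
        level_step: float = 0.04,
        **kw,
    ):
        super().__init__(grid, range_px, **kw)
        if not (0.0 < high_fraction < 1.0):
            raise ValueError("high_fraction must be in (0, 1)")
        if low_interval[1] >= high_interval[0]:
            raise ValueError("activity intervals must be disjoint (low below high)")
        if low_interval[0] <= 0:
            raise ValueError("activity intervals must be positive")
        self.high_fraction = high_fraction
        self.low_interval = tuple(map(float, low_interval))
        self.high_interval = tuple(map(float, high_interval))
        self.threshold = float(ndtri(high_fraction)) if threshold is None else float(threshold)
        self.p_level = p_level
        self.level_step = level_step

    def initial(self, rng) -> Rho1State:
        rng = np.random.default_rng(rng)
        white = self.grf.sample_white(rng)
        low = rng.uniform(*self.low_interval)
        high = rng.uniform(*self.high_interval)
        return Rho1State(white, low, high)

    @staticmethod
    def _reflect(x: float, lo: float, hi: float) -> float:
        width = hi - lo
        t = (x - lo) % (2.0 * width)
        return lo + (t if t <= width else 2.0 * width - t)

    def perturb(self, state: Rho1State, step: float, rng) -> Rho1State:
        rng = np.random.default_rng(rng)
        white = self._perturb_white(state.white, step, rng)
        low, high = state.low, state.high
        if rng.random() < self.p_level:
            if rng.random() < 0.5:
                lo, hi = self.low_interval
                low = self._reflect(low + self.level_step * (hi - lo) * rng.standard_normal(), lo, hi)
            else:
                lo, hi = self.high_interval
                high = self._reflect(high + self.level_step * (hi - lo) * rng.standard_normal(), lo, hi)
        return Rho1State(white, low, high)

    def high_mask(self, state: Rho1State) -> np.ndarray:
        return self.grf.color(state.white) < self.threshold

    def activity(self, state: Rho1State) -> ActivityImage:
        vals = np.where(self.high_mask(state), state.high, state.low)
        return ActivityImage(self.grid, vals)

    def latent(self, state: Rho1State) -> np.ndarray:
        return self.grf.color(state.white)


def realize_rho1(latent: np.ndarray, prior: TruncatedBimodalPrior, level_seed=None):
    """Populate an already-colored latent field with region levels.

    Returns ``(high_mask, image)``; the truncation and level draws match the
    prior's parameters.
    """
    rng = np.random.default_rng(level_seed)
    z = np.asarray(latent, dtype=float)
    high = z < prior.threshold
    vals = np.where(high, rng.uniform(*prior.high_interval), rng.uniform(*prior.low_interval))
    return high, ActivityImage(prior.grid, vals)


# ---------------------------------------------------------------------------
# Trimodal tissue prior (in-vivo style)
# ---------------------------------------------------------------------------

class TissueMixture:
    """Three-component marginal: lesion N(2.7, 0.13^2), soft tissue
    N(0.55, 0.15^2), lung-like U(0.06, 0.2); weights configurable.

    The quantile function is tabulated on a fine grid of activities, with the
    support truncated to positive values (the soft-tissue normal has ~1e-4
    mass below zero, which a positive activity image cannot carry).
    """

    def __init__(
        self,
        weights: tuple[float, float, float] = (0.10, 0.45, 0.45),
        lesion=(2.7, 0.13),
        tissue=(0.55, 0.15),
        lung=(0.06, 0.2),
        floor: float = 1e-3,
        table_size: int = 20001,
    ):
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("mixture weights must be positive and sum to 1")
        self.weights = weights
        self.lesion, self.tissue, self.lung = lesion, tissue, lung
        hi = lesion[0] + 8 * lesion[1]
        self._x = np.linspace(floor, hi, table_size)
        self._F = self.cdf(self._x)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        w1, w2, w3 = self.weights
        return (
            w1 * norm.cdf(x, *self.lesion)
            + w2 * norm.cdf(x, *self.tissue)
            + w3 * uniform.cdf(x, self.lung[0], self.lung[1] - self.lung[0])
        )

    def ppf(self, u) -> np.ndarray:
        """Quantile function via the tabulated CDF (monotone interpolation)."""
        return np.interp(np.asarray(u, dtype=float), self._F, self._x)


class TrimodalTissuePrior(TransformedGaussianPrior):
    """Normal-score transform of a GRF through the tissue mixture quantile."""

    def __init__(self, grid: ImageGrid, range_px: float = 8.0,
                 mixture: TissueMixture | None = None, **kw):
        self.mixture = mixture if mixture is not None else TissueMixture()
        super().__init__(grid, range_px, transform=self._transform, **kw)

    def _transform(self, z: np.ndarray) -> np.ndarray:
        return self.mixture.ppf(ndtr(z))


def realize_rho2(latent: np.ndarray, prior: TrimodalTissuePrior) -> ActivityImage:
    """Normal-score transform of an already-colored latent field."""
    z = np.asarray(latent, dtype=float)
    return ActivityImage(prior.grid, prior.mixture.ppf(ndtr(z)))
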