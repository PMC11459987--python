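"""The linear smoothing (point-spread) operator of the imaging system.

The scanner PSF is modelled as a Gaussian averaging kernel: the weight
between pixels separated by physical distance ``h`` (mm) is proportional to
``exp(-h^2 / a^2)``, where ``a`` is the kernel range in mm.  Each row of the
equivalent matrix is normalized to sum to one (rows are renormalized over
in-image pixels at the borders, so no padding data is invented), which makes
the operator a convex averaging: a spatially constant image is mapped to
itself and output extrema never exceed input extrema.

When the model grid refines the data grid by an integer factor f, the
operator convolves on the fine grid (distances measured in mm) and then
block-averages the result onto the data grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ActivityImage, ImageGrid, ReconstructedPET, block_mean


def fwhm_of_kernel(a_mm: float) -> float:
    """Full width at half maximum of ``exp(-h^2/a^2)``: ``2 a sqrt(ln 2)``."""
    if a_mm < 0:
        raise ValueError(f"kernel range must be >= 0, got {a_mm}")
    return 2.0 * a_mm * np.sqrt(np.log(2.0))


def _gaussian_stencil(a_mm: float, pixel_size_mm, support_radius_in_a: float) -> np.ndarray:
    """Unnormalized kernel stencil sampled at pixel centers, truncated at
    Euclidean distance ``support_radius_in_a * a``."""
    if a_mm == 0.0:
        return np.ones((1, 1))
    dy, dx = pixel_size_mm
    support = support_radius_in_a * a_mm
    ry = int(np.floor(support / dy))
    rx = int(np.floor(support / dx))
    yy, xx = np.meshgrid(np.arange(-ry, ry + 1) * dy, np.arange(-rx, rx + 1) * dx, indexing="ij")
    h2 = yy**2 + xx**2
    w = np.exp(-h2 / a_mm**2)
    w[h2 > support**2] = 0.0
    return w


@dataclass
class ConvolutionOperator:
    """Row-normalized Gaussian smoothing operator mapping model grid -> data grid.

    Parameters
    ----------
    a_mm : float
        Kernel range ``a`` in mm (``a=0`` gives pure aggregation; the
        identity when the grids coincide).
    model_grid, data_grid : ImageGrid
        ``model_grid`` must be an integer refinement of ``data_grid``.
    support_radius_in_a : float
        Truncation radius in units of ``a`` (weights beyond it are zero
        before renormalization).  The default 4 discards relative weights
        below ``exp(-16) ~ 1e-7``.
    """

    a_mm: float
    model_grid: ImageGrid
    data_grid: ImageGrid
    support_radius_in_a: float = 4.0
    _stencil: np.ndarray = field(init=False, repr=False)
    _row_norm: np.ndarray = field(init=False, repr=False)
    _f: int = field(init=False, repr=False)

    def __post_init__(self):
        if self.a_mm < 0:
            raise ValueError(f"kernel range must be >= 0, got {self.a_mm}")
        if self.support_radius_in_a <= 0:
            raise ValueError("support radius must be > 0")
        self._f = self.model_grid.refinement_factor_of(self.data_grid)
        self._stencil = _gaussian_stencil(
            self.a_mm, self.model_grid.pixel_size_mm, self.support_radius_in_a
        )
        # Edge renormalization: each output row averages over in-image pixels only.
        ones = np.ones(self.model_grid.shape)
        self._row_norm = ndimage.convolve(ones, self._stencil, mode="constant", cval=0.0)

    @property
    def refinement_factor(self) -> int:
        return self._f

    def apply_to_values(self, values: np.ndarray) -> np.ndarray:
        """Apply the operator to a raw fine-grid array, returning data-grid values."""
        num = ndimage.convolve(np.asarray(values, float), self._stencil, mode="constant", cval=0.0)
        fine = num / self._row_norm
        return block_mean(fine, self._f)

    def apply(self, img: ActivityImage) -> ReconstructedPET:
        """Noise-free predicted PET image of an activity image."""
        if img.grid != self.model_grid:
            raise ValueError("image grid does not match the operator's model grid")
        return ReconstructedPET(self.data_grid, self.apply_to_values(img.values), role="predicted")

    def as_matrix(self) -> np.ndarray:
        """Dense equivalent matrix (data pixels x model pixels); for small grids."""
        n_in = self.model_grid.n_pixels
        n_out = self.data_grid.n_pixels
        G = np.empty((n_out, n_in))
        basis = np.zeros(self.model_grid.shape)
        for k in range(n_in):
            basis.flat[k] = 1.0
            G[:, k] = self.apply_to_values(basis).ravel()
            basis.flat[k] = 0.0
        return G


def build_operator(
    a_mm: float,
    model_grid: ImageGrid,
    data_grid: ImageGrid | None = None,
    support_radius_in_a: float = 4.0,
) -> ConvolutionOperator:
    """Convenience constructor; ``data_grid`` defaults to the model grid (f=1)."""
    if data_grid is None:
        data_grid = model_grid
    return ConvolutionOperator(a_mm, model_grid, data_grid, support_radius_in_a)
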