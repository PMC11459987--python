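"""Core spatial containers: grids, activity images, PET images, masks.

All images are 2D, row-major ``(row, col)``.  Pixel ``(i, j)`` has its
physical center at ``((i + 0.5) * dy, (j + 0.5) * dx)`` millimetres from the
grid origin (top-left corner).  Activity concentrations are in kBq/ml and
must be strictly positive wherever a log-domain likelihood is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DomainError(ValueError):
    """A value violates a mathematical domain requirement (e.g. log of <= 0)."""


def _as_pixel_size(pixel_size_mm) -> tuple[float, float]:
    if np.isscalar(pixel_size_mm):
        pixel_size_mm = (float(pixel_size_mm), float(pixel_size_mm))
    dy, dx = (float(pixel_size_mm[0]), float(pixel_size_mm[1]))
    if dy <= 0 or dx <= 0:
        raise ValueError(f"pixel sizes must be > 0, got {(dy, dx)}")
    return (dy, dx)


@dataclass(frozen=True)
class ImageGrid:
    """A regular 2D pixel grid with physical pixel sizes in mm.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (>= 1).
    pixel_size_mm : float or (float, float)
        Pixel spacing, either a scalar (square pixels) or per-axis
        ``(row_spacing, col_spacing)``.
    """

    n_rows: int
    n_cols: int
    pixel_size_mm: tuple[float, float]

    def __post_init__(self):
        if int(self.n_rows) != self.n_rows or int(self.n_cols) != self.n_cols:
            raise ValueError("grid dimensions must be integers")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        object.__setattr__(self, "n_rows", int(self.n_rows))
        object.__setattr__(self, "n_cols", int(self.n_cols))
        object.__setattr__(self, "pixel_size_mm", _as_pixel_size(self.pixel_size_mm))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm[0] * self.pixel_size_mm[1]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Total physical size (height, width) in mm."""
        return (self.n_rows * self.pixel_size_mm[0], self.n_cols * self.pixel_size_mm[1])

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical center coordinates ``(y, x)`` of every pixel, shape (n_rows, n_cols)."""
        dy, dx = self.pixel_size_mm
        y = (np.arange(self.n_rows) + 0.5) * dy
        x = (np.arange(self.n_cols) + 0.5) * dx
        return np.meshgrid(y, x, indexing="ij")

    def refinement_factor_of(self, data_grid: "ImageGrid") -> int:
        """Return integer f such that ``self`` is an f-fold refinement of ``data_grid``.

        Raises ``ValueError`` if no such integer exists.
        """
        if self.n_rows % data_grid.n_rows or self.n_cols % data_grid.n_cols:
            raise ValueError("grids are not integer refinements of each other")
        f = self.n_rows // data_grid.n_rows
        if self.n_cols // data_grid.n_cols != f:
            raise ValueError("refinement factor differs between axes")
        exp = (data_grid.pixel_size_mm[0] / f, data_grid.pixel_size_mm[1] / f)
        if not np.allclose(exp, self.pixel_size_mm, rtol=1e-9):
            raise ValueError("pixel sizes inconsistent with integer refinement")
        return f


def refine_grid(data_grid: ImageGrid, f: int) -> ImageGrid:
    """Subdivide every pixel into ``f x f`` sub-pixels; physical extent is unchanged."""
    if int(f) != f or f < 1:
        raise ValueError(f"refinement factor must be an integer >= 1, got {f!r}")
    f = int(f)
    dy, dx = data_grid.pixel_size_mm
    return ImageGrid(data_grid.n_rows * f, data_grid.n_cols * f, (dy / f, dx / f))


def _check_values(grid: ImageGrid, values, require_positive: bool) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    if require_positive and not np.all(values > 0):
        idx = np.argwhere(~(values > 0))[0]
        raise DomainError(f"non-positive activity at pixel {tuple(idx)}")
    return values


@dataclass
class ActivityImage:
    """Model-space activity concentration (kBq/ml) on a (possibly refined) grid.

    Values must be strictly positive: the log-normal likelihood evaluates
    ``log(G @ phi)`` which requires a positive prediction everywhere.
    """

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = _check_values(self.grid, self.values, require_positive=True)


@dataclass
class ReconstructedPET:
    """Observed or predicted reconstructed PET image on the data grid (kBq/ml)."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)
    role: str = "observed"  # "observed" | "predicted"

    def __post_init__(self):
        if self.role not in ("observed", "predicted"):
            raise ValueError(f"role must be 'observed' or 'predicted', got {self.role!r}")
        self.values = _check_values(self.grid, self.values, require_positive=True)


@dataclass
class BinaryMask:
    """Pixel membership mask on a grid (region selection for calibration etc.)."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values).astype(bool)
        if values.shape != self.grid.shape:
            raise ValueError(f"mask shape {values.shape} != grid shape {self.grid.shape}")
        self.values = values

    @property
    def n_selected(self) -> int:
        return int(self.values.sum())


def aggregate_to_data_grid(img: ActivityImage, data_grid: ImageGrid) -> np.ndarray:
    """Block-average a fine-grid field onto the coarse data grid.

    Each data pixel receives the arithmetic mean of its ``f x f`` fine pixels,
    so activity concentration units (kBq/ml) are preserved.
    """
    f = img.grid.refinement_factor_of(data_grid)
    return block_mean(img.values, f)


def block_mean(values: np.ndarray, f: int) -> np.ndarray:
    """Arithmetic mean over non-overlapping ``f x f`` blocks."""
    if f == 1:
        return np.asarray(values, dtype=float).copy()
    n, m = values.shape
    return values.reshape(n // f, f, m // f, f).mean(axis=(1, 3))
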