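"""Image and configuration I/O.

Images are read from NIfTI (pixel sizes from the header) or CSV (pixel size
supplied by the caller/config).  Configuration files are YAML; a fully
resolved copy (every defaulted field filled in) is written next to the run
outputs so any run can be reproduced exactly.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import ActivityImage, BinaryMask, ImageGrid, ReconstructedPET


def _grid_from_values(values: np.ndarray, pixel_size_mm) -> ImageGrid:
    return ImageGrid(values.shape[0], values.shape[1], pixel_size_mm)


def read_image(path, pixel_size_mm=None, kind: str = "observed"):
    """Read a 2D image as :class:`ReconstructedPET` or :class:`ActivityImage`.

    ``kind`` is ``"observed"``, ``"predicted"`` or ``"activity"``.  NIfTI
    files carry their own pixel sizes; CSV files require ``pixel_size_mm``.
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2D slice, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        grid = _grid_from_values(data, (float(zooms[0]), float(zooms[1])))
    elif path.suffix == ".csv":
        if pixel_size_mm is None:
            raise ValueError(f"{path}: CSV images need pixel_size_mm from the configuration")
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        grid = _grid_from_values(data, pixel_size_mm)
    else:
        raise ValueError(f"unsupported image format: {path}")
    if kind == "activity":
        return ActivityImage(grid, data)
    return ReconstructedPET(grid, data, role=kind)


def write_image(path, grid: ImageGrid, values: np.ndarray):
    """Write a 2D field as NIfTI (pixel size in header) or CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values, dtype=float)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        affine = np.diag([grid.pixel_size_mm[0], grid.pixel_size_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(values, affine)
        img.header.set_zooms((grid.pixel_size_mm[0], grid.pixel_size_mm[1]))
        nib.save(img, str(path))
    elif path.suffix == ".csv":
        np.savetxt(path, values, delimiter=",")
    else:
        raise ValueError(f"unsupported image format: {path}")


def read_mask(path, grid: ImageGrid) -> BinaryMask:
    """Mask from a CSV 0/1 matrix or a CSV list of (row, col) indices."""
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape == grid.shape:
        return BinaryMask(grid, data > 0.5)
    if data.shape[1] == 2:
        m = np.zeros(grid.shape, dtype=bool)
        m[data[:, 0].astype(int), data[:, 1].astype(int)] = True
        return BinaryMask(grid, m)
    raise ValueError(f"mask shape {data.shape} matches neither the grid nor an index list")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(cfg: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
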