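"""Synthetic NEMA-like sphere phantoms and simulated noisy PET observations.

A phantom is a two-valued ground-truth activity image: a constant warm
background plus a set of hot circles (the central slice through the fillable
spheres of a NEMA body phantom).  Observations are simulated by smoothing
the truth with the system's Gaussian kernel and applying one draw of the
correlated log-normal noise model, so the whole calibrate/sample/analyze
pipeline can be exercised with known ground truth and no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .calibration import NoiseModel
from .grids import ActivityImage, BinaryMask, ImageGrid, ReconstructedPET
from .psf import ConvolutionOperator

#: default circle radii (mm): graded sizes whose pixel areas on a 2.08 mm grid
#: are near a NEMA central-slice series (~241, 130, 76, 43, 21, 13 pixels)
DEFAULT_RADII_MM = (18.2, 13.4, 10.2, 7.7, 5.4, 4.2)


@dataclass
class PhantomSpec:
    """Geometry and activity levels of a sphere phantom slice."""

    grid: ImageGrid
    background: float = 0.43  # kBq/ml
    sphere_activity: float = 2.77  # kBq/ml
    circles: list = field(default_factory=list)  # (center_y_mm, center_x_mm, radius_mm)

    def __post_init__(self):
        if self.background <= 0 or self.sphere_activity <= 0:
            raise ValueError("activities must be > 0")
        hy, wx = self.grid.extent_mm
        for cy, cx, r in self.circles:
            if r <= 0:
                raise ValueError("circle radius must be > 0")
            if not (0 <= cy <= hy and 0 <= cx <= wx):
                raise ValueError(f"circle center ({cy}, {cx}) outside the grid")


def default_nema_spec(grid: ImageGrid | None = None, radii_mm=None,
                      ring_radius_mm: float | None = None) -> PhantomSpec:
    """Circles of graded radius on a ring around the grid center.

    Defaults target a 90x90 grid of 2.08 mm pixels; on smaller grids the
    layout (ring radius and circle radii) is scaled down proportionally.
    """
    if grid is None:
        grid = ImageGrid(90, 90, 2.08)
    hy, wx = grid.extent_mm
    scale = min(hy, wx) / (90 * 2.08)
    if radii_mm is None:
        radii_mm = tuple(r * scale for r in DEFAULT_RADII_MM)
    if ring_radius_mm is None:
        ring_radius_mm = 55.0 * scale
    cy0, cx0 = hy / 2.0, wx / 2.0
    circles = []
    for k, r in enumerate(radii_mm):
        ang = 2.0 * np.pi * k / len(radii_mm)
        circles.append((cy0 + ring_radius_mm * np.sin(ang), cx0 + ring_radius_mm * np.cos(ang), r))
    return PhantomSpec(grid=grid, circles=circles)


def make_phantom(spec: PhantomSpec):
    """Rasterize a phantom spec.

    A pixel is high-activity iff its center lies inside a circle
    (center-containment, no anti-aliasing), so true areas are integer pixel
    counts.  Returns ``(truth, masks, areas_px)``.

    Raises ``ValueError`` for overlapping circles.
    """
    for a in range(len(spec.circles)):
        for b in range(a + 1, len(spec.circles)):
            ya, xa, ra = spec.circles[a]
            yb, xb, rb = spec.circles[b]
            if np.hypot(ya - yb, xa - xb) < ra + rb:
                raise ValueError(f"circles {a} and {b} overlap")
    yy, xx = spec.grid.pixel_centers_mm()
    values = np.full(spec.grid.shape, spec.background)
    masks = []
    areas = []
    for cy, cx, r in spec.circles:
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
        values[inside] = spec.sphere_activity
        masks.append(BinaryMask(spec.grid, inside))
        areas.append(int(inside.sum()))
    return ActivityImage(spec.grid, values), masks, areas


def simulate_observation(
    truth: ActivityImage, op: ConvolutionOperator, nm: NoiseModel, seed=None
) -> ReconstructedPET:
    """One simulated noisy reconstructed PET image of a known truth."""
    mean = op.apply(truth)
    return nm.simulate(mean, np.random.default_rng(seed))


def spec_to_json(spec: PhantomSpec) -> str:
    """Serialize the generating parameters (sidecar for simulated data)."""
    return json.dumps(
        {
            "n_rows": spec.grid.n_rows,
            "n_cols": spec.grid.n_cols,
            "pixel_size_mm": list(spec.grid.pixel_size_mm),
            "background": spec.background,
            "sphere_activity": spec.sphere_activity,
            "circles": [list(c) for c in spec.circles],
        },
        indent=2,
    )
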