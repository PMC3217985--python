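"""Binary vessel segmentation from the vesselness response and raw intensity.

A pixel is foreground iff its multiscale vesselness clears ``v_min`` and
its normalized raw intensity lies in the ``[low, high]`` band; the mask is
then cleaned by small-particle removal and bounded hole filling.

Connectivity convention: foreground 8-connected, background 4-connected
(Jordan-curve consistent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

from .raster_io import RasterImage
from .vessel_enhance import VesselnessMap

__all__ = [
    "VesselMask",
    "threshold_segment",
    "remove_small_particles",
    "fill_holes",
    "save_mask_png",
    "load_mask_png",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class VesselMask:
    """Binary segmentation grid (foreground 8-connected, background 4-connected)."""

    grid: np.ndarray
    pixel_size: float = 1.0

    #: recorded connectivity convention
    foreground_connectivity: int = 8
    background_connectivity: int = 4

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    @property
    def area(self) -> float:
        """Foreground area in calibrated units squared."""
        return self.foreground_count * self.pixel_size**2


def threshold_segment(
    vmap: VesselnessMap,
    image: RasterImage,
    low: float = 0.0,
    high: float = 1.0,
    v_min: float = 0.0,
) -> VesselMask:
    """Conjunction of the vesselness gate and the raw-intensity band.

    ``low``/``high`` are normalized intensities in [0, 1]; either gate is
    disabled at its extreme value (v_min=0, low=0, high=1).
    """
    for name, val in (("low", low), ("high", high)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    if vmap.response.shape != image.pixels.shape:
        raise ValueError("vesselness map and image dimensions differ")
    norm = image.normalized()
    grid = (vmap.response >= v_min) & (norm >= low) & (norm <= high)
    return VesselMask(grid, pixel_size=image.pixel_size)


def remove_small_particles(mask: VesselMask, min_area: int) -> VesselMask:
    """Delete 8-connected foreground components with area < ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    if min_area == 0:
        return VesselMask(mask.grid.copy(), pixel_size=mask.pixel_size)
    # remove components with area < min_area, i.e. <= min_area - 1
    grid = remove_small_objects(mask.grid, max_size=min_area - 1, connectivity=2)
    return VesselMask(grid, pixel_size=mask.pixel_size)


def fill_holes(mask: VesselMask, max_hole_area: int) -> VesselMask:
    """Fill enclosed background holes of area <= ``max_hole_area``.

    A hole is a 4-connected background component that does not touch the
    image border. ``max_hole_area=0`` is exactly the identity.
    """
    if max_hole_area < 0:
        raise ValueError("max_hole_area must be non-negative")
    grid = mask.grid.copy()
    if max_hole_area == 0:
        return VesselMask(grid, pixel_size=mask.pixel_size)

    labels, n = ndimage.label(~grid, structure=_STRUCT4)
    if n == 0:
        return VesselMask(grid, pixel_size=mask.pixel_size)
    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    fill = ~border & (counts <= max_hole_area)
    fill[0] = False  # label 0 is foreground in the background labelling
    grid[fill[labels]] = True
    return VesselMask(grid, pixel_size=mask.pixel_size)


def save_mask_png(mask: VesselMask, path) -> None:
    """Export the binary mask as an 8-bit 0/255 PNG (debug/fixture aid)."""
    from PIL import Image

    Image.fromarray(np.where(mask.grid, 255, 0).astype(np.uint8)).save(
        path, format="PNG"
    )


def load_mask_png(path, pixel_size: float = 1.0) -> VesselMask:
    """Read a 0/255 PNG written by :func:`save_mask_png`."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return VesselMask(arr > 127, pixel_size=pixel_size)
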