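"""Raster image input, tabular result output and analysis overlays.

Images are read into a canonical single-channel :class:`RasterImage` grid
(8- or 16-bit, square pixels). Results are written as CSV (canonical) or
XLSX, one row per analysed image, with the analysis parameters echoed in
dedicated columns. Overlays are written as PNG.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image, ImageDraw

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import AnalysisResult, ConvexHull
    from .segment import VesselMask
    from .skeleton_graph import SkeletonGraph

__all__ = [
    "RasterImage",
    "FormatError",
    "load_image",
    "write_results",
    "read_results",
    "render_overlay",
    "OverlayStyle",
    "RESULT_COLUMNS",
]

#: Fixed column order of the result table (bit-exact header contract).
RESULT_COLUMNS = [
    "image_id",
    "sigmas",
    "v_min",
    "low",
    "high",
    "min_particle",
    "max_hole",
    "pixel_size",
    "explant_area",
    "vessel_area",
    "vessel_density_pct",
    "total_junctions",
    "branching_index",
    "total_vessel_length",
    "average_vessel_length",
    "total_endpoints",
    "mean_lacunarity",
]

#: Fixed luminance weights for the ``luminance`` channel policy.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


class FormatError(ValueError):
    """Raised when an input image has an unsupported format or depth."""


@dataclass
class RasterImage:
    """A 2-D single-channel intensity grid with square pixels.

    Parameters
    ----------
    pixels:
        2-D array of non-negative intensities (uint8 or uint16).
    bit_depth:
        8 or 16; all intensities lie in ``[0, 2**bit_depth - 1]``.
    pixel_size:
        Physical length of one pixel edge (arbitrary units, default 1.0).
        A single scalar: the pixel aspect ratio is 1.0 by construction.
    source_id:
        Free-text provenance (usually the file name).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D grid, got {self.pixels.ndim} dims")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth: {self.bit_depth}")
        h, w = self.pixels.shape
        if h < 3 or w < 3:
            raise FormatError(f"image too small: {h}x{w} (minimum 3x3)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        lo = self.pixels.min(initial=0)
        hi = self.pixels.max(initial=0)
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def intensity_max(self) -> int:
        """Full-scale intensity for this bit depth."""
        return 2**self.bit_depth - 1

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to float64 in [0, 1] by the bit depth."""
        return self.pixels.astype(np.float64) / self.intensity_max


def _reduce_colour(arr: np.ndarray, channel_policy: str) -> np.ndarray:
    """Reduce an H x W x 3 uint8 array to one channel per policy."""
    if channel_policy == "max_channel":
        return arr.max(axis=2)
    if channel_policy == "luminance":
        w = np.asarray(LUMINANCE_WEIGHTS)
        lum = arr.astype(np.float64) @ w
        return np.rint(lum).astype(arr.dtype)
    if channel_policy.startswith("channel:"):
        i = int(channel_policy.split(":", 1)[1])
        if not 0 <= i < arr.shape[2]:
            raise FormatError(f"channel index {i} out of range for {arr.shape[2]} channels")
        return arr[:, :, i]
    raise ValueError(f"unknown channel policy: {channel_policy!r}")


def load_image(
    path: str | Path,
    channel_policy: str = "max_channel",
    pixel_size: float = 1.0,
) -> RasterImage:
    """Read a TIFF/PNG/JPEG image into a canonical greyscale grid.

    Greyscale inputs pass through unchanged (byte-identical grid); 24-bit
    colour inputs are reduced to one channel according to *channel_policy*
    (``max_channel``, ``luminance`` with weights 0.299/0.587/0.114, or
    ``channel:<i>`` for a single channel).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: {path} does not exist")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot decode image {path}: {exc}") from exc

    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"unsupported sample type {arr.dtype} in {path.name}")

    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise FormatError(
                f"unsupported channel count {arr.shape[2]} in {path.name} "
                "(expected greyscale or 24-bit RGB)"
            )
        if depth != 8:
            raise FormatError(f"colour images must be 24-bit, got {depth*3}-bit")
        arr = _reduce_colour(arr, channel_policy)
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path.name}")

    return RasterImage(arr, bit_depth=depth, pixel_size=pixel_size, source_id=path.name)


def _result_row(res: "AnalysisResult") -> dict:
    cfg = res.config_echo
    return {
        "image_id": res.image_id,
        "sigmas": ";".join(format(s, "g") for s in cfg.sigmas),
        "v_min": cfg.v_min,
        "low": cfg.low,
        "high": cfg.high,
        "min_particle": cfg.min_particle,
        "max_hole": cfg.max_hole,
        "pixel_size": cfg.pixel_size,
        "explant_area": res.explant_area,
        "vessel_area": res.vessel_area,
        "vessel_density_pct": res.vessel_density,
        "total_junctions": res.total_junctions,
        "branching_index": res.branching_index,
        "total_vessel_length": res.total_vessel_length,
        "average_vessel_length": res.average_vessel_length,
        "total_endpoints": res.total_endpoints,
        "mean_lacunarity": res.mean_lacunarity,
    }


def results_frame(results: Sequence["AnalysisResult"]) -> pd.DataFrame:
    """Result rows as a DataFrame in the documented column order."""
    if len(results) == 0:
        raise ValueError("need at least one result")
    return pd.DataFrame([_result_row(r) for r in results], columns=RESULT_COLUMNS)


def write_results(
    results: Sequence["AnalysisResult"],
    path: str | Path,
    format: str = "csv",
) -> Path:
    """Write one row per result to CSV (canonical) or XLSX (mirror).

    Floats are printed with 17 significant digits so a CSV round-trip is
    exact to well beyond 12 significant digits.
    """
    path = Path(path)
    frame = results_frame(results)
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "xlsx":
        frame.to_excel(path, index=False, sheet_name="results")
    else:
        raise ValueError(f"unknown output format: {format!r}")
    return path


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Re-read a results table written by :func:`write_results`."""
    if format == "csv":
        return pd.read_csv(path)
    if format == "xlsx":
        return pd.read_excel(path)
    raise ValueError(f"unknown output format: {format!r}")


@dataclass(frozen=True)
class OverlayStyle:
    outline_rgb: tuple[int, int, int] = (255, 255, 0)
    skeleton_rgb: tuple[int, int, int] = (255, 0, 0)
    junction_rgb: tuple[int, int, int] = (0, 96, 255)
    hull_rgb: tuple[int, int, int] = (0, 255, 128)
    junction_radius: int = 2
    draw_hull: bool = True


def _outline(mask_grid: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-neighbour outside the mask."""
    from scipy import ndimage

    eroded = ndimage.binary_erosion(
        mask_grid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
        border_value=0,
    )
    return mask_grid & ~eroded


def render_overlay_array(
    image: RasterImage,
    mask: "VesselMask | None" = None,
    skeleton: "SkeletonGraph | None" = None,
    hull: "ConvexHull | None" = None,
    style: OverlayStyle | None = None,
) -> np.ndarray:
    """Render the analysis overlay as an H x W x 3 uint8 array.

    Pure with respect to its inputs: the analysis state is never modified.
    """
    style = style or OverlayStyle()
    base = np.rint(image.normalized() * 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=2)

    if mask is not None:
        if mask.grid.shape != image.pixels.shape:
            raise ValueError(
                f"mask shape {mask.grid.shape} != image shape {image.pixels.shape}"
            )
        rgb[_outline(mask.grid)] = style.outline_rgb

    pil = Image.fromarray(rgb)
    draw = ImageDraw.Draw(pil)

    if hull is not None and style.draw_hull and len(hull.vertices):
        # vertices are (row, col); PIL wants (x, y) = (col, row)
        pts = [(float(c), float(r)) for r, c in hull.vertices]
        draw.polygon(pts, outline=style.hull_rgb)

    out = np.asarray(pil).copy()

    if skeleton is not None:
        if skeleton.skeleton.shape != image.pixels.shape:
            raise ValueError(
                f"skeleton shape {skeleton.skeleton.shape} != image shape "
                f"{image.pixels.shape}"
            )
        out[skeleton.skeleton] = style.skeleton_rgb
        pil = Image.fromarray(out)
        draw = ImageDraw.Draw(pil)
        rad = style.junction_radius
        for node in skeleton.junctions:
            r, c = node.representative
            draw.ellipse([c - rad, r - rad, c + rad, r + rad], fill=style.junction_rgb)
        out = np.asarray(pil).copy()

    return out


def render_overlay(
    image: RasterImage,
    mask: "VesselMask | None",
    skeleton: "SkeletonGraph | None",
    hull: "ConvexHull | None",
    path: str | Path,
    style: OverlayStyle | None = None,
) -> Path:
    """Render and write the overlay PNG; returns the written path."""
    arr = render_overlay_array(image, mask, skeleton, hull, style)
    path = Path(path)
    Image.fromarray(arr).save(path, format="PNG")
    return path
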