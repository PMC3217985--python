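"""Morphometric and spatial metrics, and the end-to-end analysis pipeline.

Computes the nine reported parameters from a vessel mask and its skeleton
graph: explant (convex hull) area, vessel area, vessel density, junction
and endpoint counts, branching index (junctions per unit hull area), total
and average vessel length, and mean lacunarity over a ladder of box sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import ConvexHull as _QhullConvexHull

from .config import AnalysisConfig
from .raster_io import RasterImage
from .segment import VesselMask, fill_holes, remove_small_particles, threshold_segment
from .skeleton_graph import SkeletonGraph, build_graph
from .vessel_enhance import VesselnessMap, VesselnessParams, multiscale_vesselness

__all__ = [
    "ConvexHull",
    "LacunarityCurve",
    "LengthMetrics",
    "AnalysisResult",
    "PipelineRun",
    "NoVesselsError",
    "UndefinedLacunarityError",
    "convex_hull",
    "vessel_density",
    "branching_index",
    "length_metrics",
    "lacunarity",
    "default_box_sizes",
    "analyze",
    "run_pipeline",
]


class NoVesselsError(RuntimeError):
    """The mask became empty at some pipeline stage."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"no vessels detected (mask empty after stage: {stage})")


class UndefinedLacunarityError(ValueError):
    """No foreground mass inside the lacunarity region."""


@dataclass(frozen=True)
class ConvexHull:
    """Convex hull of the foreground pixel corners.

    ``vertices`` are (row, col) corner coordinates in hull order; ``area``
    is in calibrated units squared (shoelace x pixel_size^2). The corner
    convention guarantees hull area >= foreground area.
    """

    vertices: np.ndarray
    area: float

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0


@dataclass(frozen=True)
class LacunarityCurve:
    box_sizes: tuple[int, ...]
    lambdas: tuple[float, ...]

    @property
    def mean_lacunarity(self) -> float:
        """Unweighted arithmetic mean of lambda over all box sizes."""
        return float(np.mean(self.lambdas))

    def pairs(self) -> list[tuple[int, float]]:
        return list(zip(self.box_sizes, self.lambdas))


class LengthMetrics(NamedTuple):
    total_length: float
    average_length: float
    endpoint_count: int
    junction_count: int


@dataclass
class AnalysisResult:
    """The nine reported parameters plus provenance."""

    explant_area: float
    vessel_area: float
    vessel_density: float
    total_junctions: int
    branching_index: float
    total_vessel_length: float
    average_vessel_length: float
    total_endpoints: int
    mean_lacunarity: float
    lacunarity_curve: tuple[tuple[int, float], ...]
    config_echo: AnalysisConfig
    image_id: str
    branch_count: int = 0
    warnings: tuple[str, ...] = ()


@dataclass
class PipelineRun:
    """Full pipeline output: the result plus all intermediate products."""

    result: AnalysisResult
    vesselness: VesselnessMap
    mask: VesselMask
    graph: SkeletonGraph
    hull: ConvexHull
    stage_stats: dict


def _shoelace(vertices: np.ndarray) -> float:
    x = vertices[:, 1]
    y = vertices[:, 0]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def convex_hull(mask: VesselMask) -> ConvexHull:
    """Hull of the four corner points of every foreground pixel.

    Vertices from a standard hull solver; area by the shoelace formula,
    scaled by pixel_size^2. An empty mask yields a defined-empty hull
    (area 0); density/branching index error out downstream.
    """
    fg = np.argwhere(mask.grid)
    if len(fg) == 0:
        return ConvexHull(vertices=np.empty((0, 2)), area=0.0)
    corners = np.concatenate(
        [fg, fg + (0, 1), fg + (1, 0), fg + (1, 1)]
    ).astype(np.float64)
    corners = np.unique(corners, axis=0)
    hull = _QhullConvexHull(corners)
    verts = corners[hull.vertices]
    area = _shoelace(verts) * mask.pixel_size**2
    return ConvexHull(vertices=verts * mask.pixel_size, area=area)


def vessel_density(mask: VesselMask, hull: ConvexHull) -> float:
    """Percentage of the hull area occupied by vessel pixels, in (0, 100]."""
    if hull.is_empty or hull.area <= 0:
        raise ValueError("vessel density undefined for an empty hull")
    return 100.0 * mask.area / hull.area


def branching_index(
    junction_count: int, hull: ConvexHull, unit_area: float = 1.0e4
) -> float:
    """Junctions per ``unit_area`` of hull area (default 10^4 area units)."""
    if hull.is_empty or hull.area <= 0:
        raise ValueError("branching index undefined for an empty hull")
    if unit_area <= 0:
        raise ValueError("unit_area must be positive")
    return junction_count / hull.area * unit_area


def length_metrics(graph: SkeletonGraph) -> LengthMetrics:
    """Total/average vessel length (calibrated) and node counts.

    With zero branches the average is defined as 0 and a warning is issued.
    """
    total = graph.total_length_px * graph.pixel_size
    if graph.branch_count == 0:
        warnings.warn("no branches in skeleton graph; average length set to 0")
        average = 0.0
    else:
        average = total / graph.branch_count
    return LengthMetrics(total, average, graph.endpoint_count, graph.junction_count)


def default_box_sizes(region_shape: tuple[int, int]) -> tuple[int, ...]:
    """Powers of 2 from 2 up to half the smaller region dimension.

    Falls back to (1,) when no power of 2 fits (tiny regions).
    """
    limit = min(region_shape) // 2
    sizes = []
    r = 2
    while r <= limit:
        sizes.append(r)
        r *= 2
    return tuple(sizes) if sizes else (1,)


def _region_bounds(mask: VesselMask, region: str) -> tuple[int, int, int, int]:
    if region == "image":
        h, w = mask.grid.shape
        return 0, 0, h, w
    if region == "hull_bbox":
        fg = np.argwhere(mask.grid)
        if len(fg) == 0:
            raise UndefinedLacunarityError("no foreground pixels in mask")
        r0, c0 = fg.min(axis=0)
        r1, c1 = fg.max(axis=0) + 1
        return int(r0), int(c0), int(r1), int(c1)
    raise ValueError(f"unknown lacunarity region: {region!r}")


def lacunarity(
    mask: VesselMask,
    region: str = "hull_bbox",
    box_sizes: Sequence[int] | None = None,
) -> LacunarityCurve:
    """Grid box-counting lacunarity curve over the chosen region.

    The region is tiled with non-overlapping r x r boxes anchored at the
    region origin (partial edge boxes discarded). With box masses M
    (foreground counts), ``lambda(r) = N * sum(M^2) / sum(M)^2``, i.e.
    <M^2>/<M>^2 — >= 1 on any nonempty mask, and exactly 1 when all box
    masses are equal.
    """
    r0, c0, r1, c1 = _region_bounds(mask, region)
    sub = mask.grid[r0:r1, c0:c1]
    h, w = sub.shape
    if h == 0 or w == 0:
        raise UndefinedLacunarityError("empty lacunarity region")
    if box_sizes is None:
        box_sizes = default_box_sizes((h, w))
    box_sizes = tuple(int(b) for b in box_sizes)
    if any(b < 1 for b in box_sizes):
        raise ValueError("box sizes must be >= 1")
    if any(b > min(h, w) for b in box_sizes):
        raise ValueError(
            f"box sizes {box_sizes} exceed region dimensions {(h, w)}"
        )

    lambdas = []
    for r in box_sizes:
        nr, nc = h // r, w // r
        trimmed = sub[: nr * r, : nc * r].astype(np.int64)
        masses = trimmed.reshape(nr, r, nc, r).sum(axis=(1, 3)).ravel()
        total = masses.sum()
        if total == 0:
            raise UndefinedLacunarityError(
                f"no foreground mass at box size {r} within the region"
            )
        lam = len(masses) * float((masses.astype(np.float64) ** 2).sum()) / float(total) ** 2
        lambdas.append(lam)
    return LacunarityCurve(box_sizes=box_sizes, lambdas=tuple(lambdas))


def run_pipeline(image: RasterImage, config: AnalysisConfig) -> PipelineRun:
    """Run the full analysis and keep all intermediate products.

    vesselness -> threshold -> particle removal -> hole filling ->
    skeletonize/classify/merge/trace -> metrics. Pure function of
    (image, config); deterministic for fixed inputs.
    """
    if image.pixel_size != config.pixel_size:
        image = RasterImage(
            image.pixels,
            bit_depth=image.bit_depth,
            pixel_size=config.pixel_size,
            source_id=image.source_id,
        )
    stats: dict = {}

    params = VesselnessParams(
        sigmas=config.sigmas, beta=config.beta, c=config.c, gamma=config.gamma
    )
    vmap = multiscale_vesselness(image, params)

    mask = threshold_segment(vmap, image, low=config.low, high=config.high, v_min=config.v_min)
    stats["threshold_segment"] = mask.foreground_count
    if mask.foreground_count == 0:
        raise NoVesselsError("threshold_segment")

    mask = remove_small_particles(mask, config.min_particle)
    stats["remove_small_particles"] = mask.foreground_count
    if mask.foreground_count == 0:
        raise NoVesselsError("remove_small_particles")

    mask = fill_holes(mask, config.max_hole)
    stats["fill_holes"] = mask.foreground_count

    graph = build_graph(mask)
    stats["skeleton_pixels"] = int(graph.skeleton.sum())

    hull = convex_hull(mask)
    lengths = length_metrics(graph)
    curve = lacunarity(mask, region=config.lacunarity_region, box_sizes=config.lacunarity_boxes)

    warns: tuple[str, ...] = ()
    if graph.branch_count == 0:
        warns = ("no branches traced; average vessel length reported as 0",)

    result = AnalysisResult(
        explant_area=hull.area,
        vessel_area=mask.area,
        vessel_density=vessel_density(mask, hull),
        total_junctions=lengths.junction_count,
        branching_index=branching_index(lengths.junction_count, hull, config.unit_area),
        total_vessel_length=lengths.total_length,
        average_vessel_length=lengths.average_length,
        total_endpoints=lengths.endpoint_count,
        mean_lacunarity=curve.mean_lacunarity,
        lacunarity_curve=tuple(curve.pairs()),
        config_echo=config,
        image_id=image.source_id,
        branch_count=graph.branch_count,
        warnings=warns,
    )
    return PipelineRun(result, vmap, mask, graph, hull, stats)


def analyze(image: RasterImage, config: AnalysisConfig) -> AnalysisResult:
    """Run the full pipeline and return the AnalysisResult only."""
    return run_pipeline(image, config).result
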