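"""Synthetic tubular-network fixtures with exact ground truth.

Generates raster images of tubes and branching trees (Gaussian
cross-section around analytic centerlines) together with the exact
centerline geometry, junction/endpoint counts and total centerline length,
so every pipeline stage is testable without external data.

Two deliberate constraints make end-to-end recovery a fair target: segment
directions are snapped to the 8 compass directions (the 1/sqrt(2) skeleton
step rule is then length-exact along straight runs) and junctions are kept
at least three tube widths apart.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .raster_io import RasterImage

__all__ = [
    "NetworkSpec",
    "GroundTruth",
    "Segment",
    "Fixture",
    "GenerationError",
    "generate_tube",
    "generate_tree",
    "degrade",
    "save_fixture",
]

_SQRT2 = math.sqrt(2.0)

# 8 compass directions as unit vectors (row, col)
_DIRS = [
    (0.0, 1.0),
    (_SQRT2 / 2, _SQRT2 / 2),
    (1.0, 0.0),
    (_SQRT2 / 2, -_SQRT2 / 2),
    (0.0, -1.0),
    (-_SQRT2 / 2, -_SQRT2 / 2),
    (-1.0, 0.0),
    (-_SQRT2 / 2, _SQRT2 / 2),
]


class GenerationError(RuntimeError):
    """The requested network cannot be placed on the canvas."""


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of a random branching-tree fixture."""

    seed: int = 0
    canvas: tuple[int, int] = (320, 320)
    n_primary: int = 2
    branch_prob: float = 0.7
    max_depth: int = 3
    width_range: tuple[float, float] = (2.5, 3.5)
    seg_len_range: tuple[float, float] = (30.0, 50.0)
    intensity: int = 200
    background: int = 10
    noise_sd: float = 0.0
    speck_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width_range[0] < 1:
            raise ValueError("tube widths must be >= 1")
        if not self.intensity > self.background:
            raise ValueError("intensity must exceed background")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")


@dataclass(frozen=True)
class Segment:
    """One straight centerline segment of the network tree."""

    seg_id: int
    parent: int | None  # parent segment id (None for roots)
    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    width: float
    depth: int

    @property
    def length(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])


@dataclass(frozen=True)
class GroundTruth:
    """Exact topology and geometry of a generated fixture."""

    centerline_pixels: frozenset
    junction_count: int
    endpoint_count: int
    total_length: float
    branch_widths: tuple[float, ...]
    terminal_count: int = 0


@dataclass
class Fixture:
    """A generated raster plus its ground truth and segment geometry."""

    image: RasterImage
    truth: GroundTruth
    segments: list[Segment] = field(default_factory=list)
    spec: NetworkSpec | None = None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _sample_polyline(points: list[tuple[float, float]], step: float = 0.5) -> np.ndarray:
    """Points at ~`step` px spacing along a polyline, endpoints included."""
    out = []
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        seg_len = math.hypot(r1 - r0, c1 - c0)
        n = max(int(math.ceil(seg_len / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        out.append(np.column_stack([r0 + t * (r1 - r0), c0 + t * (c1 - c0)]))
    return np.concatenate(out)


def _polyline_length(points: list[tuple[float, float]]) -> float:
    return float(
        sum(
            math.hypot(b[0] - a[0], b[1] - a[1])
            for a, b in zip(points[:-1], points[1:])
        )
    )


def _centerline_pixels(points: np.ndarray) -> frozenset:
    px = np.rint(points).astype(int)
    return frozenset((int(r), int(c)) for r, c in px)


def _point_segment_dist(pts_r, pts_c, a, b) -> np.ndarray:
    """Distance from grid points to segment a-b (arrays broadcast)."""
    ar, ac = a
    br, bc = b
    dr, dc = br - ar, bc - ac
    denom = dr * dr + dc * dc
    if denom == 0:
        return np.hypot(pts_r - ar, pts_c - ac)
    t = ((pts_r - ar) * dr + (pts_c - ac) * dc) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(pts_r - (ar + t * dr), pts_c - (ac + t * dc))


def _rasterize(
    polylines: list[tuple[list[tuple[float, float]], float]],
    canvas: tuple[int, int],
    intensity: int,
    background: int,
) -> np.ndarray:
    """Max of Gaussian tube profiles (sd = width/2) over a background level."""
    h, w = canvas
    acc = np.zeros((h, w), dtype=np.float64)
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    for points, width in polylines:
        sd = width / 2.0
        reach = int(math.ceil(4 * sd)) + 2
        for a, b in zip(points[:-1], points[1:]):
            r0 = max(int(min(a[0], b[0])) - reach, 0)
            r1 = min(int(max(a[0], b[0])) + reach + 1, h)
            c0 = max(int(min(a[1], b[1])) - reach, 0)
            c1 = min(int(max(a[1], b[1])) + reach + 1, w)
            if r0 >= r1 or c0 >= c1:
                continue
            rr = rows[r0:r1][:, None]
            cc = cols[c0:c1][None, :]
            d = _point_segment_dist(rr, cc, a, b)
            prof = np.exp(-(d**2) / (2.0 * sd**2))
            np.maximum(acc[r0:r1, c0:c1], prof, out=acc[r0:r1, c0:c1])
    img = background + (intensity - background) * acc
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# single tubes
# ---------------------------------------------------------------------------


def generate_tube(
    kind: str = "horizontal",
    length: int = 50,
    width: float = 4.0,
    radius: float = 40.0,
    canvas: tuple[int, int] = (96, 96),
    intensity: int = 200,
    background: int = 10,
    source_id: str = "tube",
) -> Fixture:
    """A single tube with an analytic centerline and exact ground truth.

    ``kind``: 'horizontal' (``length`` pixels, centerline length
    ``length - 1``), 'diagonal' (45 degrees, ``length`` diagonal steps,
    centerline length ``length * sqrt(2)``) or 'quarter_circle' (radius
    ``radius``, arc length ~ pi * radius / 2 by polyline summation).
    """
    h, w = canvas
    if kind == "horizontal":
        r = h // 2
        c0 = (w - length) // 2
        if c0 < 1 or c0 + length > w - 1:
            raise ValueError("tube exceeds canvas")
        points = [(float(r), float(c0)), (float(r), float(c0 + length - 1))]
    elif kind == "diagonal":
        r0 = (h - length) // 2
        c0 = (w - length) // 2
        if r0 < 1 or r0 + length > h - 1 or c0 < 1 or c0 + length > w - 1:
            raise ValueError("tube exceeds canvas")
        points = [(float(r0), float(c0)), (float(r0 + length), float(c0 + length))]
    elif kind == "quarter_circle":
        cr, cc = h * 0.75, w * 0.25
        if radius + 4 * width > min(cr, w - cc):
            raise ValueError("tube exceeds canvas")
        theta = np.linspace(-np.pi / 2, 0.0, 181)
        points = [
            (float(cr + radius * np.sin(t)), float(cc + radius * np.cos(t)))
            for t in theta
        ]
    else:
        raise ValueError(f"unknown tube kind: {kind!r}")

    pts = _sample_polyline(points)
    img = _rasterize([(points, width)], canvas, intensity, background)
    truth = GroundTruth(
        centerline_pixels=_centerline_pixels(pts),
        junction_count=0,
        endpoint_count=2,
        total_length=_polyline_length(points),
        branch_widths=(width,),
        terminal_count=1,
    )
    raster = RasterImage(img, bit_depth=8, source_id=source_id)
    seg = [
        Segment(i, None if i == 0 else i - 1, points[i], points[i + 1], width, 0)
        for i in range(len(points) - 1)
    ]
    return Fixture(image=raster, truth=truth, segments=seg)


# ---------------------------------------------------------------------------
# branching trees
# ---------------------------------------------------------------------------


def _snap(dir_idx: int, length: float) -> tuple[tuple[float, float], float]:
    """Snap a segment to the lattice so its digital path length is exact."""
    dr, dc = _DIRS[dir_idx]
    if dir_idx % 2 == 0:  # axis direction
        n = max(int(round(length)), 1)
        return (dr * n, dc * n), float(n)
    n = max(int(round(length / _SQRT2)), 1)  # diagonal steps
    step = _SQRT2 / 2
    return (round(dr / step) * n * 1.0, round(dc / step) * n * 1.0), n * _SQRT2


class _TreeBuilder:
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.maxw = spec.width_range[1]
        self.margin = int(math.ceil(6 + 3 * self.maxw))
        self.segments: list[Segment] = []
        self.children: dict[int, list[int]] = {}
        self.clearance = 3.0 * self.maxw
        self.adj_skip = 4.5 * self.maxw

    def _in_canvas(self, pts: np.ndarray) -> bool:
        h, w = self.spec.canvas
        m = self.margin
        return bool(
            (pts[:, 0] >= m).all()
            and (pts[:, 0] <= h - 1 - m).all()
            and (pts[:, 1] >= m).all()
            and (pts[:, 1] <= w - 1 - m).all()
        )

    def _clear(self, a, b, parent_id: int | None) -> bool:
        pts = _sample_polyline([a, b], step=1.0)
        if not self._in_canvas(pts):
            return False
        adjacent_ids = set()
        if parent_id is not None:
            adjacent_ids.add(parent_id)
            adjacent_ids.update(self.children.get(parent_id, ()))
        for seg in self.segments:
            d = _point_segment_dist(pts[:, 0], pts[:, 1], seg.start, seg.end)
            if seg.seg_id in adjacent_ids:
                # ignore the shared-node neighbourhood of parent/sibling
                from_node = np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
                d = d[from_node >= self.adj_skip]
                if d.size == 0:
                    continue
            if float(d.min()) < self.clearance:
                return False
        return True

    def _add(self, a, b, width, depth, parent_id) -> int:
        sid = len(self.segments)
        self.segments.append(Segment(sid, parent_id, a, b, width, depth))
        self.children[sid] = []
        if parent_id is not None:
            self.children[parent_id].append(sid)
        return sid

    @staticmethod
    def _cyc_dist(a: int, b: int) -> int:
        d = abs(a - b) % 8
        return min(d, 8 - d)

    def grow(self, a, dirs: list[int], depth: int, width: float, parent_id) -> int | None:
        """Try to place one segment from *a*; recurse into children.

        Candidate directions are tried in order with progressively shorter
        lengths; if none clears the separation constraint the node stays a
        leaf (the ground truth reflects the placed topology). Returns the
        placed direction index, or None.
        """
        spec = self.spec
        placed = None
        for dir_idx in dirs:
            for frac in (1.0, 0.8, 0.65):
                length = self.rng.uniform(*spec.seg_len_range) * frac
                (dr, dc), _ = _snap(dir_idx, length)
                b = (a[0] + dr, a[1] + dc)
                if self._clear(a, b, parent_id):
                    placed = (b, dir_idx)
                    break
            if placed:
                break
        if placed is None:
            return None
        b, d = placed
        sid = self._add(a, b, width, depth, parent_id)
        if depth < spec.max_depth and self.rng.random() < spec.branch_prob:
            # children turn +-45 deg, falling back to +-90 deg; any pair of
            # placed arms stays >= 90 deg apart so junctions resolve cleanly
            d1 = self.grow(b, [(d - 1) % 8, (d - 2) % 8], depth + 1, width, sid)
            cands = [
                c
                for c in ((d + 1) % 8, (d + 2) % 8)
                if d1 is None or self._cyc_dist(c, d1) >= 2
            ]
            self.grow(b, cands, depth + 1, width, sid)
        return d

    def _root_anchors(self) -> list[tuple[float, float]]:
        """Evenly spread root positions (keeps cohorts of trees comparable)."""
        h, w = self.spec.canvas
        n = self.spec.n_primary
        cells = int(math.ceil(math.sqrt(n)))
        anchors = []
        for i in range(n):
            gr, gc = divmod(i, cells)
            anchors.append(
                (
                    h * (gr + 0.5) / math.ceil(n / cells),
                    w * (gc + 0.5) / cells,
                )
            )
        return anchors

    def place_roots(self) -> None:
        spec = self.spec
        h, w = spec.canvas
        m = self.margin
        for anchor in self._root_anchors():
            width = float(self.rng.uniform(*spec.width_range))
            d0 = int(self.rng.integers(0, 8))
            placed = False
            for attempt in range(60):
                jitter = 0.0 if attempt == 0 else 12.0
                a = (
                    float(np.clip(round(anchor[0] + self.rng.uniform(-jitter, jitter)), m, h - 1 - m)),
                    float(np.clip(round(anchor[1] + self.rng.uniform(-jitter, jitter)), m, w - 1 - m)),
                )
                if self.grow(a, [(d0 + k) % 8 for k in range(8)], 0, width, None) is not None:
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    "cannot place a primary branch with the required junction "
                    "separation; enlarge the canvas or reduce n_primary"
                )


def _tree_truth(segments: list[Segment], children: dict[int, list[int]]) -> GroundTruth:
    n_junction = sum(1 for sid in children if len(children[sid]) == 2)
    leaves = [sid for sid in children if len(children[sid]) == 0]
    roots = [s for s in segments if s.parent is None]
    pts = (
        np.concatenate([_sample_polyline([s.start, s.end]) for s in segments])
        if segments
        else np.empty((0, 2))
    )
    return GroundTruth(
        centerline_pixels=_centerline_pixels(pts),
        junction_count=n_junction,
        endpoint_count=len(roots) + len(leaves),
        total_length=float(sum(s.length for s in segments)),
        branch_widths=tuple(s.width for s in segments),
        terminal_count=len(leaves),
    )


def _render_tree(
    segments: list[Segment],
    spec: NetworkSpec,
    rng: np.random.Generator,
    source_id: str,
) -> RasterImage:
    polylines = [([s.start, s.end], s.width) for s in segments]
    img = _rasterize(polylines, spec.canvas, spec.intensity, spec.background)
    img = _apply_specks(img, segments, spec, rng)
    img = _apply_noise(img, spec.noise_sd, rng)
    return RasterImage(img, bit_depth=8, source_id=source_id)


def _apply_noise(img: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return img
    noisy = img.astype(np.float64) + rng.normal(0.0, sd, size=img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _apply_specks(
    img: np.ndarray,
    segments: list[Segment],
    spec: NetworkSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    if spec.speck_rate <= 0:
        return img
    h, w = img.shape
    n = int(round(spec.speck_rate * h * w))
    maxw = spec.width_range[1]
    out = img.copy()
    placed = 0
    for _ in range(n * 30):
        if placed >= n:
            break
        r = float(rng.uniform(2, h - 3))
        c = float(rng.uniform(2, w - 3))
        if segments:
            dmin = min(
                float(_point_segment_dist(np.array([r]), np.array([c]), s.start, s.end)[0])
                for s in segments
            )
            if dmin < 5.0 * maxw:
                continue
        rad = float(rng.uniform(0.6, 1.2))
        rr, cc = np.ogrid[0:h, 0:w]
        disc = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        out[disc] = spec.intensity
        placed += 1
    return out


def generate_tree(spec: NetworkSpec) -> Fixture:
    """A random branching network with exact topology ground truth.

    Reproducible per seed; junctions are separated by at least three times
    the maximum tube width so the skeleton resolves each one individually.
    A branch that cannot be placed under that constraint terminates instead
    (the ground truth reflects the placed topology).
    """
    rng = np.random.default_rng(spec.seed)
    builder = _TreeBuilder(spec, rng)
    builder.place_roots()
    truth = _tree_truth(builder.segments, builder.children)
    image = _render_tree(builder.segments, spec, rng, f"tree-seed{spec.seed}")
    return Fixture(image=image, truth=truth, segments=builder.segments, spec=spec)


# ---------------------------------------------------------------------------
# degradations (inhibitor-phenotype stand-ins)
# ---------------------------------------------------------------------------


def degrade(fixture: Fixture, mode: str, magnitude: float, seed: int = 0) -> Fixture:
    """Controlled degradations of a fixture; returns a new Fixture.

    Modes: ``sparsify`` (prune a fraction of terminal branches before
    re-rasterization; at most one child per parent is pruned while
    possible), ``thin`` (multiply tube widths), ``add_specks`` (sprinkle
    small bright particles clear of the vessels), ``add_noise`` (additive
    Gaussian, clipped; magnitude 0 is the identity).
    """
    if fixture.spec is None:
        raise ValueError("degrade needs a fixture produced by generate_tree")
    spec = fixture.spec
    rng = np.random.default_rng(seed)

    if mode == "sparsify":
        children: dict[int, list[int]] = {s.seg_id: [] for s in fixture.segments}
        for s in fixture.segments:
            if s.parent is not None:
                children[s.parent].append(s.seg_id)
        terminals = [sid for sid, ch in children.items() if not ch]
        n_prune = int(round(magnitude * len(terminals)))
        by_parent: dict = {}
        for sid in terminals:
            by_parent.setdefault(fixture.segments[sid].parent, []).append(sid)
        # prefer one terminal per parent so pruning exposes no new terminals
        first_choice = [rng.choice(v) for v in by_parent.values()]
        rng.shuffle(first_choice)
        pruned = set(int(x) for x in first_choice[:n_prune])
        rest = [t for t in terminals if t not in pruned]
        rng.shuffle(rest)
        for sid in rest:
            if len(pruned) >= n_prune:
                break
            pruned.add(int(sid))
        keep = [s for s in fixture.segments if s.seg_id not in pruned]
        new_children: dict[int, list[int]] = {s.seg_id: [] for s in keep}
        for s in keep:
            if s.parent is not None:
                new_children[s.parent].append(s.seg_id)
        truth = _tree_truth(keep, new_children)
        image = _render_tree(keep, spec, rng, fixture.image.source_id + "-sparsified")
        return Fixture(image=image, truth=truth, segments=keep, spec=spec)

    if mode == "thin":
        segs = [replace(s, width=max(s.width * magnitude, 1.0)) for s in fixture.segments]
        children = {s.seg_id: [] for s in segs}
        for s in segs:
            if s.parent is not None:
                children[s.parent].append(s.seg_id)
        truth = _tree_truth(segs, children)
        image = _render_tree(segs, spec, rng, fixture.image.source_id + "-thin")
        return Fixture(image=image, truth=truth, segments=segs, spec=spec)

    if mode == "add_specks":
        speck_spec = replace(spec, speck_rate=magnitude)
        img = _apply_specks(
            fixture.image.pixels.copy(), fixture.segments, speck_spec, rng
        )
        raster = RasterImage(
            img, bit_depth=8, pixel_size=fixture.image.pixel_size,
            source_id=fixture.image.source_id + "-specks",
        )
        return Fixture(image=raster, truth=fixture.truth,
                       segments=list(fixture.segments), spec=spec)

    if mode == "add_noise":
        if magnitude == 0:
            raster = RasterImage(
                fixture.image.pixels.copy(), bit_depth=fixture.image.bit_depth,
                pixel_size=fixture.image.pixel_size, source_id=fixture.image.source_id,
            )
            return Fixture(image=raster, truth=fixture.truth,
                           segments=list(fixture.segments), spec=spec)
        img = _apply_noise(fixture.image.pixels, magnitude, rng)
        raster = RasterImage(
            img, bit_depth=8, pixel_size=fixture.image.pixel_size,
            source_id=fixture.image.source_id + "-noise",
        )
        return Fixture(image=raster, truth=fixture.truth,
                       segments=list(fixture.segments), spec=spec)

    raise ValueError(f"unknown degradation mode: {mode!r}")


def save_fixture(fixture: Fixture, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Export a fixture as TIFF plus a JSON ground-truth sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}.tif"
    js = out_dir / f"{stem}.json"
    tifffile.imwrite(tif, fixture.image.pixels)
    truth = fixture.truth
    js.write_text(
        json.dumps(
            {
                "junction_count": truth.junction_count,
                "endpoint_count": truth.endpoint_count,
                "total_length": truth.total_length,
                "terminal_count": truth.terminal_count,
                "branch_widths": list(truth.branch_widths),
                "centerline_pixels": sorted(map(list, truth.centerline_pixels)),
            },
            indent=1,
        )
    )
    return tif, js
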