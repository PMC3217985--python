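"""Skeletonization and skeleton-graph analysis.

The vessel mask is thinned to a one-pixel-wide, topology-preserving
skeleton whose pixels are classified by their number of 8-neighbours
(<2 endpoint, =2 slab, >2 junction). Adjacent junction pixels are merged
into single junction nodes, and slab chains are traced into branches — a
branch is a segment between two nodes (junction/endpoint) or a node-free
closed loop. Branch lengths use the Euclidean step rule (1 for axis steps,
sqrt(2) for diagonal steps); at a junction end the branch is extended
through the cluster to the node's representative pixel.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .segment import VesselMask

__all__ = [
    "BACKGROUND",
    "ENDPOINT",
    "SLAB",
    "JUNCTION",
    "JunctionNode",
    "Branch",
    "SkeletonGraph",
    "skeletonize",
    "classify_pixels",
    "merge_junction_clusters",
    "trace_branches",
    "build_graph",
    "branch_table",
    "write_branch_table",
    "save_skeleton_png",
]

BACKGROUND, ENDPOINT, SLAB, JUNCTION = 0, 1, 2, 3

_SQRT2 = math.sqrt(2.0)
_STRUCT8 = np.ones((3, 3), dtype=bool)
# 8-neighbour offsets in row-major order (deterministic traversal)
_N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class JunctionNode:
    """One merged branching point: an 8-connected cluster of junction pixels."""

    representative: tuple[int, int]
    members: frozenset


@dataclass(frozen=True)
class Branch:
    """One vessel segment: an 8-connected pixel path between two nodes.

    ``length`` is in pixel units; ``closed`` marks loops (coincident ends).
    """

    path: tuple[tuple[int, int], ...]
    length: float
    closed: bool = False

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.path[0], self.path[-1]


@dataclass
class SkeletonGraph:
    skeleton: np.ndarray
    junctions: list[JunctionNode] = field(default_factory=list)
    endpoints: list[tuple[int, int]] = field(default_factory=list)
    branches: list[Branch] = field(default_factory=list)
    pixel_size: float = 1.0

    @property
    def skeleton_pixels(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in np.argwhere(self.skeleton)}

    @property
    def junction_count(self) -> int:
        return len(self.junctions)

    @property
    def endpoint_count(self) -> int:
        return len(self.endpoints)

    @property
    def branch_count(self) -> int:
        return len(self.branches)

    @property
    def total_length_px(self) -> float:
        return float(sum(b.length for b in self.branches))


# ring of 8 neighbours with 4-neighbours at even indices (E, N, W, S)
_RING = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


def _is_simple(skel: np.ndarray, r: int, c: int) -> bool:
    """Yokoi connectivity test: removal of (r, c) preserves 8-topology."""
    h, w = skel.shape
    x = [
        bool(skel[r + dr, c + dc]) if 0 <= r + dr < h and 0 <= c + dc < w else False
        for dr, dc in _RING
    ]
    xb = [0 if v else 1 for v in x]
    cn = sum(
        xb[k] - xb[k] * xb[(k + 1) % 8] * xb[(k + 2) % 8] for k in (0, 2, 4, 6)
    )
    return cn == 1


def _thin_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove simple pixels from residual 2x2 blocks (row-major, in place).

    Thinning can leave 2x2 staircase blocks; every block pixel whose removal
    preserves topology is deleted. Blocks whose pixels are all topologically
    necessary (e.g. four arms meeting in a 2x2 core) are kept: topology
    preservation outranks strict thinness.
    """
    changed = True
    while changed:
        changed = False
        blocks = np.argwhere(
            skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        )
        for r, c in blocks:
            for pr, pc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)):
                if not (
                    skel[r, c] and skel[r, c + 1] and skel[r + 1, c] and skel[r + 1, c + 1]
                ):
                    break  # block already dissolved by an earlier removal
                if _is_simple(skel, pr, pc):
                    skel[pr, pc] = False
                    changed = True
                    break
    return skel


def skeletonize(mask: VesselMask) -> np.ndarray:
    """Topology-preserving thinning to a one-pixel-wide skeleton.

    Deterministic for a fixed input; an empty mask yields an empty skeleton.
    """
    if not mask.grid.any():
        return np.zeros_like(mask.grid, dtype=bool)
    skel = _sk_skeletonize(mask.grid).astype(bool)
    return _thin_blocks(skel)


def classify_pixels(skeleton: np.ndarray) -> np.ndarray:
    """Label each skeleton pixel by its count of 8-neighbours in the skeleton.

    <2 neighbours -> ENDPOINT (isolated pixels included), =2 -> SLAB,
    >2 -> JUNCTION. Background stays 0.
    """
    skel = np.asarray(skeleton, dtype=bool)
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    counts = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant", cval=0)
    labels = np.zeros(skel.shape, dtype=np.uint8)
    labels[skel & (counts < 2)] = ENDPOINT
    labels[skel & (counts == 2)] = SLAB
    labels[skel & (counts > 2)] = JUNCTION
    return labels


def merge_junction_clusters(labels: np.ndarray) -> list[JunctionNode]:
    """Merge 8-connected junction pixels into nodes.

    The node representative is the cluster centroid rounded to the nearest
    member pixel (ties broken row-major).
    """
    comp, n = ndimage.label(labels == JUNCTION, structure=_STRUCT8)
    nodes: list[JunctionNode] = []
    for idx in range(1, n + 1):
        members = [(int(r), int(c)) for r, c in np.argwhere(comp == idx)]
        members.sort()
        cr = sum(m[0] for m in members) / len(members)
        cc = sum(m[1] for m in members) / len(members)
        rep = min(members, key=lambda m: ((m[0] - cr) ** 2 + (m[1] - cc) ** 2, m))
        nodes.append(JunctionNode(representative=rep, members=frozenset(members)))
    return nodes


def _step(a: tuple[int, int], b: tuple[int, int]) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_length(path) -> float:
    return float(sum(_step(path[i], path[i + 1]) for i in range(len(path) - 1)))


def _cluster_path(entry: tuple[int, int], rep: tuple[int, int], members: frozenset):
    """Shortest 8-connected path from *entry* to *rep* within the cluster."""
    if entry == rep:
        return [entry]
    dist = {entry: 0.0}
    prev: dict = {}
    heap = [(0.0, entry)]
    while heap:
        d, p = heapq.heappop(heap)
        if p == rep:
            break
        if d > dist.get(p, math.inf):
            continue
        for dr, dc in _N8:
            q = (p[0] + dr, p[1] + dc)
            if q not in members:
                continue
            nd = d + _step(p, q)
            if nd < dist.get(q, math.inf):
                dist[q] = nd
                prev[q] = p
                heapq.heappush(heap, (nd, q))
    path = [rep]
    while path[-1] != entry:
        path.append(prev[path[-1]])
    path.reverse()
    return path  # entry ... rep


def trace_branches(
    skeleton: np.ndarray,
    labels: np.ndarray | None = None,
    junctions: list[JunctionNode] | None = None,
    pixel_size: float = 1.0,
) -> SkeletonGraph:
    """Assign every slab pixel to exactly one branch and measure lengths.

    Branches terminate at endpoint pixels or at junction-node
    representatives (paths through a junction cluster are completed by the
    shortest within-cluster route). Node-free cycles become single closed
    branches carrying the full cycle length; isolated pixels become
    endpoints with a zero-length branch. Traversal order is row-major
    everywhere, so the result is deterministic.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if labels is None:
        labels = classify_pixels(skel)
    if junctions is None:
        junctions = merge_junction_clusters(labels)

    cluster_of: dict[tuple[int, int], int] = {}
    for i, node in enumerate(junctions):
        for m in node.members:
            cluster_of[m] = i

    h, w = skel.shape

    def n8_in(p):
        for dr, dc in _N8:
            r, c = p[0] + dr, p[1] + dc
            if 0 <= r < h and 0 <= c < w and skel[r, c]:
                yield (r, c)

    def lab(p) -> int:
        return int(labels[p[0], p[1]])

    endpoints = [(int(r), int(c)) for r, c in np.argwhere(labels == ENDPOINT)]
    node_pixels = sorted(
        [(int(r), int(c)) for r, c in np.argwhere((labels == ENDPOINT) | (labels == JUNCTION))]
    )

    branches: list[Branch] = []
    visited_slab: set[tuple[int, int]] = set()

    def finish(chain: list) -> None:
        """Extend junction ends to node representatives and record the branch."""
        path = list(chain)
        if lab(path[0]) == JUNCTION:
            node = junctions[cluster_of[path[0]]]
            ext = _cluster_path(path[0], node.representative, node.members)
            path = list(reversed(ext))[:-1] + path  # rep ... entry, entry dropped once
        if lab(path[-1]) == JUNCTION:
            node = junctions[cluster_of[path[-1]]]
            ext = _cluster_path(path[-1], node.representative, node.members)
            path = path + ext[1:]
        closed = len(path) > 1 and path[0] == path[-1]
        branches.append(Branch(tuple(path), _path_length(path), closed=closed))

    # 1) branches leaving node pixels through slab chains
    for p in node_pixels:
        for q in sorted(n8_in(p)):
            if lab(q) != SLAB or q in visited_slab:
                continue
            chain = [p, q]
            visited_slab.add(q)
            prev, cur = p, q
            while lab(cur) == SLAB:
                nxt = next(n for n in n8_in(cur) if n != prev)
                chain.append(nxt)
                if lab(nxt) == SLAB:
                    visited_slab.add(nxt)
                prev, cur = cur, nxt
            finish(chain)

    # 2) directly adjacent node pixels (no slab between them)
    for p in node_pixels:
        for q in sorted(n8_in(p)):
            if lab(q) not in (ENDPOINT, JUNCTION) or q <= p:
                continue
            if lab(p) == JUNCTION and lab(q) == JUNCTION:
                continue  # same cluster by construction
            finish([p, q])

    # 3) isolated pixels: endpoints with a zero-length branch
    for p in node_pixels:
        if lab(p) == ENDPOINT and not any(True for _ in n8_in(p)):
            branches.append(Branch((p,), 0.0))

    # 4) node-free cycles: every remaining slab has exactly two neighbours
    remaining = sorted(
        (int(r), int(c))
        for r, c in np.argwhere(labels == SLAB)
        if (int(r), int(c)) not in visited_slab
    )
    remaining_set = set(remaining)
    for start in remaining:
        if start not in remaining_set:
            continue
        chain = [start]
        remaining_set.discard(start)
        prev, cur = None, start
        while True:
            nxt = min(n for n in n8_in(cur) if n != prev)
            if nxt == start:
                break
            chain.append(nxt)
            remaining_set.discard(nxt)
            prev, cur = cur, nxt
        length = _path_length(chain) + _step(chain[-1], start)
        branches.append(Branch(tuple(chain) + (start,), length, closed=True))

    return SkeletonGraph(
        skeleton=skel,
        junctions=junctions,
        endpoints=sorted(endpoints),
        branches=branches,
        pixel_size=pixel_size,
    )


def build_graph(mask: VesselMask) -> SkeletonGraph:
    """Skeletonize a mask and analyse it into a full SkeletonGraph."""
    skel = skeletonize(mask)
    labels = classify_pixels(skel)
    junctions = merge_junction_clusters(labels)
    return trace_branches(skel, labels, junctions, pixel_size=mask.pixel_size)


def branch_table(graph: SkeletonGraph) -> "list[dict]":
    """Branch rows (id, end coordinates, length) for CSV export/debugging."""
    rows = []
    for i, b in enumerate(graph.branches):
        (r0, c0), (r1, c1) = b.endpoints
        rows.append(
            {
                "branch_id": i,
                "start_row": r0,
                "start_col": c0,
                "end_row": r1,
                "end_col": c1,
                "length_px": b.length,
                "closed": b.closed,
            }
        )
    return rows


def write_branch_table(graph: SkeletonGraph, path) -> None:
    """Write the branch table as CSV."""
    import csv

    rows = branch_table(graph)
    fields = [
        "branch_id", "start_row", "start_col", "end_row", "end_col",
        "length_px", "closed",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)


def save_skeleton_png(graph: SkeletonGraph, path) -> None:
    """Export the skeleton as an 8-bit 0/255 PNG mask."""
    from PIL import Image

    Image.fromarray(
        np.where(graph.skeleton, 255, 0).astype(np.uint8)
    ).save(path, format="PNG")
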