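"""Independent brute-force reference implementations used only by tests.

Everything here enumerates neighbours, paths and components directly with
pure-Python loops over coordinate sets, deliberately avoiding the package's
vectorised code paths.
"""

from __future__ import annotations

import heapq
import math

import numpy as np

SQRT2 = math.sqrt(2.0)


def nbrs8(p):
    r, c = p
    return [
        (r + dr, c + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]


def nbrs4(p):
    r, c = p
    return [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]


def step(a, b):
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def flood_components(pixels: set, connectivity: int = 8) -> list[set]:
    """Connected components of a pixel set by explicit flood fill."""
    nb = nbrs8 if connectivity == 8 else nbrs4
    remaining = set(pixels)
    comps = []
    while remaining:
        start = min(remaining)
        comp = {start}
        stack = [start]
        while stack:
            q = stack.pop()
            for r in nb(q):
                if r in remaining and r not in comp:
                    comp.add(r)
                    stack.append(r)
        remaining -= comp
        comps.append(comp)
    return comps


def remove_small_oracle(grid: np.ndarray, min_area: int) -> np.ndarray:
    """Brute-force small-particle removal (8-connected components)."""
    pixels = {(int(r), int(c)) for r, c in np.argwhere(grid)}
    out = np.zeros_like(grid, dtype=bool)
    for comp in flood_components(pixels, 8):
        if len(comp) >= min_area:
            for r, c in comp:
                out[r, c] = True
    return out


def fill_holes_oracle(grid: np.ndarray, max_hole_area: int) -> np.ndarray:
    """Brute-force hole filling: flood background from the border (4-conn)."""
    h, w = grid.shape
    bg = {(r, c) for r in range(h) for c in range(w) if not grid[r, c]}
    out = grid.copy()
    if max_hole_area == 0:
        return out
    for comp in flood_components(bg, 4):
        touches = any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp)
        if not touches and len(comp) <= max_hole_area:
            for r, c in comp:
                out[r, c] = True
    return out


def mc_polygon_area(vertices: np.ndarray, n: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo area of a convex polygon (point-in-hull integration)."""
    rng = np.random.default_rng(seed)
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n, 2))
    # inside a convex polygon iff on the same side of every edge
    inside = np.ones(n, dtype=bool)
    m = len(vertices)
    for i in range(m):
        a = vertices[i]
        b = vertices[(i + 1) % m]
        cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        sign = np.sign(cross)
        sign[sign == 0] = 1
        if i == 0:
            ref = sign
        inside &= sign == ref
    box = float(np.prod(hi - lo))
    return box * inside.mean()


# ---------------------------------------------------------------------------
# brute-force skeleton analysis
# ---------------------------------------------------------------------------


def _cluster_walk_length(entry, rep, comp) -> float:
    """Shortest within-cluster path length entry -> rep (tiny Dijkstra)."""
    if entry == rep:
        return 0.0
    dist = {entry: 0.0}
    heap = [(0.0, entry)]
    while heap:
        d, p = heapq.heappop(heap)
        if p == rep:
            return d
        if d > dist.get(p, math.inf):
            continue
        for q in nbrs8(p):
            if q in comp:
                nd = d + step(p, q)
                if nd < dist.get(q, math.inf):
                    dist[q] = nd
                    heapq.heappush(heap, (nd, q))
    raise AssertionError("cluster not connected")


def skeleton_stats(skel: np.ndarray) -> tuple[int, int, int, float]:
    """(junction nodes, endpoints, branches, total length) by enumeration.

    Follows the documented conventions: neighbour-count classification,
    8-connected junction clusters with centroid-nearest representatives,
    branch lengths by the 1/sqrt(2) step rule extended to cluster
    representatives, node-free cycles as closed branches, isolated pixels
    as endpoints with zero-length branches.
    """
    S = {(int(r), int(c)) for r, c in np.argwhere(np.asarray(skel, dtype=bool))}
    deg = {p: sum(q in S for q in nbrs8(p)) for p in S}
    ends = {p for p in S if deg[p] < 2}
    juncs = {p for p in S if deg[p] > 2}
    slabs = {p for p in S if deg[p] == 2}

    clusters = flood_components(juncs, 8)
    cluster_of = {}
    reps = []
    for i, comp in enumerate(clusters):
        cr = sum(p[0] for p in comp) / len(comp)
        cc = sum(p[1] for p in comp) / len(comp)
        rep = min(sorted(comp), key=lambda m: ((m[0] - cr) ** 2 + (m[1] - cc) ** 2, m))
        reps.append(rep)
        for p in comp:
            cluster_of[p] = i

    def end_extension(p) -> float:
        if p in juncs:
            i = cluster_of[p]
            return _cluster_walk_length(p, reps[i], clusters[i])
        return 0.0

    lengths: list[float] = []
    used: set = set()
    node_px = sorted(ends | juncs)

    # slab chains out of nodes (used-check inside the loop: a chain can
    # return to the same node through a second slab neighbour)
    for p in node_px:
        for q in sorted(nbrs8(p)):
            if q not in slabs or q in used:
                continue
            path = [p, q]
            used.add(q)
            prev, cur = p, q
            while cur in slabs:
                nxt = [n for n in nbrs8(cur) if n in S and n != prev][0]
                path.append(nxt)
                if nxt in slabs:
                    used.add(nxt)
                prev, cur = cur, nxt
            total = math.fsum(step(a, b) for a, b in zip(path[:-1], path[1:]))
            lengths.append(total + end_extension(path[0]) + end_extension(path[-1]))

    # direct node-node adjacencies
    for p in node_px:
        for q in sorted(n for n in nbrs8(p) if n in (ends | juncs) and n > p):
            if p in juncs and q in juncs:
                continue
            lengths.append(step(p, q) + end_extension(p) + end_extension(q))

    # isolated pixels
    for p in sorted(ends):
        if deg[p] == 0:
            lengths.append(0.0)

    # node-free cycles
    remaining = slabs - used
    for comp in flood_components(remaining, 8):
        ordered = sorted(comp)
        start = ordered[0]
        path = [start]
        prev, cur = None, start
        while True:
            nxt = min(n for n in nbrs8(cur) if n in comp and n != prev)
            if nxt == start:
                break
            path.append(nxt)
            prev, cur = cur, nxt
        total = math.fsum(step(a, b) for a, b in zip(path[:-1], path[1:]))
        lengths.append(total + step(path[-1], start))

    return len(clusters), len(ends), len(lengths), float(math.fsum(lengths))
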