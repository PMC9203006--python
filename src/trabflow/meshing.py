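"""Quality triangulation of polygonal fluid domains.

Conforming triangulations are built from the exact boundary polylines (no
boundary node is added or moved, so the persistent boundary node identity
of a :class:`~trabflow.geometry.MovingBoundary` survives meshing) plus a
hexagonal interior lattice kept clear of the boundary, triangulated with a
Delaunay pass, clipped to the domain, and relaxed by Laplacian smoothing.
Interior clearance and the lattice spacing are tied to the local boundary
segment length, which keeps element quality high; boundary-edge recovery
is verified and locally repaired by thinning interior points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Polygon

__all__ = ["Mesh", "MeshingError", "mesh_domain", "min_angle_deg"]


class MeshingError(ValueError):
    """Meshing failed (invalid input or unrecoverable boundary)."""


@dataclass
class Mesh:
    """Triangulation: ``points`` (n,2); ``triangles`` (m,3) CCW; the first
    ``n_boundary`` points are the input boundary nodes in input order;
    ``loops`` lists their index ranges per closed loop."""

    points: np.ndarray
    triangles: np.ndarray
    n_boundary: int
    loops: list[np.ndarray]
    target_h: float

    def boundary_edges(self) -> np.ndarray:
        edges = []
        for loop in self.loops:
            edges.append(np.stack([loop, np.roll(loop, -1)], axis=1))
        return np.vstack(edges)

    def areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))


def min_angle_deg(mesh: Mesh) -> float:
    """Smallest interior angle over all elements (degrees)."""
    p = mesh.points[mesh.triangles]
    angles = []
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.sum(a * b, axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return float(np.min(angles))


def _hex_lattice(bounds, h: float) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    dy = h * np.sqrt(3.0) / 2.0
    rows = []
    y = y0 + 0.5 * dy
    row = 0
    while y < y1:
        xs = np.arange(x0 + (0.25 + 0.5 * (row % 2)) * h, x1, h)
        rows.append(np.stack([xs, np.full_like(xs, y)], axis=1))
        y += dy
        row += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def mesh_domain(shell: np.ndarray,
                holes: list[np.ndarray] | None = None,
                resolution: float | None = None,
                smooth_iters: int = 2,
                max_retries: int = 6) -> Mesh:
    """Triangulate the region bounded by ``shell`` minus any ``holes``.

    ``resolution`` is the target interior edge length (um); it defaults to
    the median boundary segment length. Boundary nodes are preserved
    verbatim and every boundary segment appears as an element edge.
    """
    shell = np.asarray(shell, dtype=float)
    holes = [np.asarray(h, dtype=float) for h in (holes or [])]
    if shell.ndim != 2 or shell.shape[0] < 3:
        raise MeshingError("shell must be a closed polyline with >= 3 nodes")
    ring = LineString(np.vstack([shell, shell[:1]]))
    if not ring.is_simple:
        raise MeshingError("self-intersecting boundary polyline")
    poly = Polygon(shell, holes)
    if not poly.is_valid or poly.area <= 0:
        raise MeshingError("invalid domain polygon (check holes vs shell)")

    b_pts = np.vstack([shell] + holes) if holes else shell
    loops = []
    start = 0
    for arr in [shell] + holes:
        loops.append(np.arange(start, start + arr.shape[0]))
        start += arr.shape[0]
    seg_len = np.concatenate([
        np.linalg.norm(np.roll(b_pts[l], -1, axis=0) - b_pts[l], axis=1)
        for l in loops])
    h = float(resolution) if resolution else float(np.median(seg_len))
    if h <= 0:
        raise MeshingError("resolution must be > 0")

    interior_region = poly.buffer(-0.55 * h)
    cand = _hex_lattice(poly.bounds, h)
    if cand.size and not interior_region.is_empty:
        keep = shapely.contains_xy(interior_region, cand[:, 0], cand[:, 1])
        interior = cand[keep]
    else:
        interior = np.empty((0, 2))

    required = set()
    for l in loops:
        for i in range(l.size):
            a, b = l[i], l[(i + 1) % l.size]
            required.add((min(a, b), max(a, b)))

    for attempt in range(max_retries):
        pts = np.vstack([b_pts, interior]) if interior.size else b_pts
        tri = Delaunay(pts)
        cent = pts[tri.simplices].mean(axis=1)
        inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        simplices = tri.simplices[inside]
        present = set()
        for t in simplices:
            for k in range(3):
                a, b = t[k], t[(k + 1) % 3]
                present.add((min(a, b), max(a, b)))
        missing = required - present
        if not missing:
            break
        # thin interior points crowding the unrecovered boundary edges
        bad = np.ones(interior.shape[0], dtype=bool)
        for (a, b) in missing:
            mid = 0.5 * (b_pts[a] + b_pts[b])
            d = np.linalg.norm(interior - mid, axis=1)
            bad &= d > 1.2 * h * (attempt + 1)
        if bad.all():  # nothing left to remove near the edge
            raise MeshingError(
                f"could not recover {len(missing)} boundary edges")
        interior = interior[bad]
    else:
        raise MeshingError("boundary edge recovery failed")

    # Laplacian smoothing of interior points (boundary fixed), re-triangulating
    nb = b_pts.shape[0]
    for _ in range(smooth_iters):
        if interior.size == 0:
            break
        neigh_sum = np.zeros_like(pts)
        neigh_cnt = np.zeros(pts.shape[0])
        for k in range(3):
            a = simplices[:, k]
            b = simplices[:, (k + 1) % 3]
            np.add.at(neigh_sum, a, pts[b])
            np.add.at(neigh_sum, b, pts[a])
            np.add.at(neigh_cnt, a, 1)
            np.add.at(neigh_cnt, b, 1)
        moved = neigh_sum[nb:] / np.maximum(neigh_cnt[nb:, None], 1)
        ok = shapely.contains_xy(interior_region, moved[:, 0], moved[:, 1])
        interior = np.where(ok[:, None], moved, pts[nb:])
        pts = np.vstack([b_pts, interior])
        tri = Delaunay(pts)
        cent = pts[tri.simplices].mean(axis=1)
        inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        simplices = tri.simplices[inside]
        present = set()
        for t in simplices:
            for k in range(3):
                a, b = t[k], t[(k + 1) % 3]
                present.add((min(a, b), max(a, b)))
        if required - present:
            raise MeshingError("boundary edge lost during smoothing")

    # drop unused points, keep boundary first
    used = np.zeros(pts.shape[0], dtype=bool)
    used[:nb] = True
    used[simplices.ravel()] = True
    remap = -np.ones(pts.shape[0], dtype=int)
    remap[used] = np.arange(used.sum())
    pts = pts[used]
    simplices = remap[simplices]

    # orient CCW
    p = pts[simplices]
    signed = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = signed < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    return Mesh(points=pts, triangles=np.ascontiguousarray(simplices),
                n_boundary=nb, loops=loops, target_h=h)
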