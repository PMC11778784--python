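"""Vectorized geometric primitives shared across modules.

All coordinates are physical micrometres in ``(z, y, x)`` component order,
matching the voxel-spacing order of the image axes. Orientation-sensitive
quantities (signed angles, left/right labels) are consistent as long as
every input vector uses the same component order.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def polyline_nearest(
    queries: np.ndarray, line: np.ndarray, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nearest point on a polyline (segment-wise) for each query point.

    Returns ``(dist, arc, foot, seg)``: distance, arclength of the foot
    point along the polyline, foot coordinates, and segment index.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    line = np.asarray(line, dtype=float)
    if len(line) < 2:
        raise ValueError("polyline needs at least 2 points")
    a = line[:-1]  # (K,3)
    d = line[1:] - a  # (K,3)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(np.einsum("ij,ij->i", line[1:] - line[:-1], line[1:] - line[:-1])))])
    n = len(queries)
    dist = np.empty(n)
    arc = np.empty(n)
    foot = np.empty((n, 3))
    seg = np.empty(n, dtype=np.intp)
    for i0 in range(0, n, chunk):
        q = queries[i0 : i0 + chunk]  # (m,3)
        # t: (m,K) projection parameter clamped to the segment
        t = np.einsum("mj,kj->mk", q, d) - np.einsum("kj,kj->k", a, d)
        t = np.clip(t / seg_len2, 0.0, 1.0)
        f = a[None, :, :] + t[:, :, None] * d[None, :, :]  # (m,K,3)
        diff = q[:, None, :] - f
        d2 = np.einsum("mkj,mkj->mk", diff, diff)
        k = np.argmin(d2, axis=1)
        m = np.arange(len(q))
        dist[i0 : i0 + chunk] = np.sqrt(d2[m, k])
        foot[i0 : i0 + chunk] = f[m, k]
        arc[i0 : i0 + chunk] = cum[k] + t[m, k] * np.sqrt(seg_len2[k])
        seg[i0 : i0 + chunk] = k
    return dist, arc, foot, seg


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from points ``p (n,3)`` to triangles ``tri (n,3,3)``.

    Pairwise: point i against triangle i (Ericson's closest-point test).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.shape == p.shape else pts
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab)[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w_ac)[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + np.nan_to_num(w_bc)[:, None] * (c - b))  # edge BC
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = vb / denom
        w = vc / denom
    interior = a + np.nan_to_num(v)[:, None] * ab + np.nan_to_num(w)[:, None] * ac
    assign(np.ones(len(p), dtype=bool), interior)  # face interior
    return np.linalg.norm(p - closest, axis=1)


class TriangleDistanceQuery:
    """Exact point-to-surface distance via KD-tree candidate pruning.

    An upper bound from the nearest mesh vertex limits the ball of candidate
    triangles (by centroid), so the reported minimum is exact, independent
    of traversal order.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.intp)
        self.tri = self.vertices[self.faces]  # (M,3,3)
        self.centroids = self.tri.mean(axis=1)
        # max distance from any centroid to its triangle's vertices
        self.tri_radius = np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max()
        self._vert_tree = cKDTree(self.vertices)
        self._cent_tree = cKDTree(self.centroids)

    def distance(self, points: np.ndarray, chunk: int = 4096) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(points))
        for i0 in range(0, len(points), chunk):
            q = points[i0 : i0 + chunk]
            ub, _ = self._vert_tree.query(q)
            lists = self._cent_tree.query_ball_point(q, ub + self.tri_radius + 1e-9)
            for j, (p, cand) in enumerate(zip(q, lists)):
                cand = np.asarray(cand, dtype=np.intp)
                d = _point_triangle_distance(
                    np.broadcast_to(p, (len(cand), 3)).copy(), self.tri[cand]
                )
                out[i0 + j] = d.min()
        return out


def signed_angle_in_plane(v: np.ndarray, ref: np.ndarray, normal: np.ndarray) -> float:
    """Signed angle (degrees, in (-180, 180]) from ``ref`` to ``v`` about ``normal``.

    Both vectors are projected onto the plane orthogonal to ``normal`` first.
    """
    n = normalize(normal)
    v = np.asarray(v, dtype=float) - np.dot(v, n) * n
    r = np.asarray(ref, dtype=float) - np.dot(ref, n) * n
    if np.linalg.norm(v) == 0 or np.linalg.norm(r) == 0:
        raise ValueError("vector projects to zero in the requested plane")
    ang = np.degrees(np.arctan2(np.dot(np.cross(r, v), n), np.dot(r, v)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
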