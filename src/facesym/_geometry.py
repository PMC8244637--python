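"""Vectorized closest-point-on-surface queries.

kd-tree candidate search over triangle centroids followed by an exact
point-to-triangle distance on the candidate set.  On the smooth,
roughly uniform meshes this package works with, a modest candidate
count is ample; the returned point always lies exactly on some triangle
of the mesh.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point on triangle ``tri[i]`` to ``points[i]``.

    points: (n, 3); tri: (n, 3, 3).  Ericson's barycentric clamping,
    vectorized over n.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (d3 >= 0) & (d4 <= d3) & ~done
    out[m] = b[m]
    done |= m
    m = (d6 >= 0) & (d5 <= d6) & ~done
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceProjector:
    """Project query points to their closest points on a triangulated surface."""

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray, n_candidates: int = 16):
        self.vertices = np.asarray(vertices, float)
        self.triangles = np.asarray(triangles, np.int64)
        self.corners = self.vertices[self.triangles]  # (t, 3, 3)
        centroids = self.corners.mean(axis=1)
        self._tree = cKDTree(centroids)
        self.n_candidates = min(n_candidates, len(self.triangles))

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest points, distances) for each query point."""
        points = np.asarray(points, float)
        _, cand = self._tree.query(points, k=self.n_candidates)
        if cand.ndim == 1:
            cand = cand[:, None]
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tri = self.corners[cand.reshape(-1)]
        closest = closest_point_on_triangles(flat_pts, flat_tri).reshape(n, k, 3)
        d2 = np.sum((closest - points[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        return closest[rows, best], np.sqrt(d2[rows, best])


def brute_force_point_mesh_distance(points: np.ndarray, vertices: np.ndarray,
                                    triangles: np.ndarray) -> np.ndarray:
    """Exact point-to-mesh distance testing every triangle (oracle; O(n·t))."""
    points = np.asarray(points, float)
    corners = np.asarray(vertices, float)[np.asarray(triangles, np.int64)]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        cp = closest_point_on_triangles(np.broadcast_to(p, (len(corners), 3)).copy(), corners)
        out[i] = np.sqrt(np.min(np.sum((cp - p) ** 2, axis=1)))
    return out
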