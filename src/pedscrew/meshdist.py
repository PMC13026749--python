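"""Exact nearest-point queries against triangle soups.

Vectorised closest-point-on-triangle (the classic barycentric region
decomposition), brute-forced over all faces in point chunks.  Exact, with
no spatial index dependency; adequate for the mesh sizes this package
works with (10^3-10^4 faces).
"""

from __future__ import annotations

import numpy as np

__all__ = ["closest_on_triangles", "closest_on_mesh"]


def _closest_chunk(p: np.ndarray, a, b, c):
    """Closest points for a (n,1,3) point chunk against (1,F,3) triangles."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
        t_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    for arr in (t_ab, t_ac, t_bc, v, w):
        np.nan_to_num(arr, copy=False)

    out = a + ab * v[..., None] + ac * w[..., None]  # face interior default
    cond_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(cond_bc[..., None], b + (c - b) * t_bc[..., None], out)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + ac * t_ac[..., None], out)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + ab * t_ab[..., None], out)
    cond_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(cond_c[..., None], np.broadcast_to(c, out.shape), out)
    cond_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(cond_b[..., None], np.broadcast_to(b, out.shape), out)
    cond_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(cond_a[..., None], np.broadcast_to(a, out.shape), out)
    return out


def closest_on_triangles(points: np.ndarray, tri_verts: np.ndarray, chunk: int = 32):
    """Closest point, distance and face index for each query point.

    Parameters: ``points`` (n, 3); ``tri_verts`` (F, 3, 3).  Returns
    ``(closest (n, 3), dist (n,), face (n,))``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tv = np.asarray(tri_verts, dtype=float)
    a = tv[None, :, 0, :]
    b = tv[None, :, 1, :]
    c = tv[None, :, 2, :]
    n = points.shape[0]
    closest = np.empty((n, 3))
    dist = np.empty(n)
    face = np.empty(n, dtype=int)
    for lo in range(0, n, chunk):
        p = points[lo : lo + chunk, None, :]
        cand = _closest_chunk(p, a, b, c)  # (m, F, 3)
        d2 = np.sum((cand - p) ** 2, axis=2)
        j = np.argmin(d2, axis=1)
        ii = np.arange(p.shape[0])
        closest[lo : lo + chunk] = cand[ii, j]
        dist[lo : lo + chunk] = np.sqrt(d2[ii, j])
        face[lo : lo + chunk] = j
    return closest, dist, face


def closest_on_mesh(points: np.ndarray, mesh):
    """Closest surface point on a trimesh mesh (no spatial index needed)."""
    return closest_on_triangles(points, mesh.triangles)
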