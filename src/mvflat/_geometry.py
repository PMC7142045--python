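"""Shared low-level geometry kernels (triangle areas, barycentrics, distances)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "triangle_areas_3d",
    "signed_areas_2d",
    "unique_edges",
    "barycentric_3d",
    "barycentric_2d",
    "point_triangle_distances",
    "align_rigid_2d",
]


def triangle_areas_3d(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unsigned areas of 3D triangles, in the square of the coordinate unit."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)


def signed_areas_2d(uv: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed areas of 2D triangles (positive = counter-clockwise)."""
    a = uv[triangles[:, 0]]
    b = uv[triangles[:, 1]]
    c = uv[triangles[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


def unique_edges(triangles: np.ndarray) -> np.ndarray:
    """Unique undirected edges (E, 2) with i < j, sorted lexicographically."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def barycentric_3d(point: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``point`` w.r.t. a 3D triangle (3, 3).

    The point is first projected onto the triangle's plane; coordinates are
    exact for points on the plane.
    """
    a, b, c = tri
    v0, v1 = b - a, c - a
    v2 = np.asarray(point, dtype=float) - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    denom = d00 * d11 - d01 * d01
    if denom <= 0:
        raise ValueError("degenerate triangle in barycentric computation")
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.array([1.0 - v - w, v, w])


def barycentric_2d(point: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of a 2D point w.r.t. a 2D triangle (3, 2)."""
    a, b, c = tri
    det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    if det == 0:
        raise ValueError("degenerate triangle in barycentric computation")
    v = ((point[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (point[1] - a[1])) / det
    w = ((b[0] - a[0]) * (point[1] - a[1]) - (point[0] - a[0]) * (b[1] - a[1])) / det
    return np.array([1.0 - v - w, v, w])


def point_triangle_distances(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between points and 3D triangles.

    Parameters
    ----------
    points : (N, 3) array
    tris : (M, 3, 3) array of triangle vertex coordinates

    Returns
    -------
    (N, M) array of distances to the closest point on each (solid) triangle.

    Vectorized form of the classic closest-point-on-triangle region test
    (edge/vertex/face Voronoi regions of the triangle).
    """
    points = np.asarray(points, dtype=float)
    tris = np.asarray(tris, dtype=float)
    a = tris[:, 0][None, :, :]          # (1, M, 3)
    b = tris[:, 1][None, :, :]
    c = tris[:, 2][None, :, :]
    p = points[:, None, :]              # (N, 1, 3)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)

    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)

    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_edge_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_edge_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        denom = va + vb + vc
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)

    # Region masks, evaluated in priority order (vertex, edge, face).
    in_a = (d1 <= 0) & (d2 <= 0)
    in_b = (d3 >= 0) & (d4 <= d3)
    in_c = (d6 >= 0) & (d5 <= d6)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    closest = a + v_face[..., None] * ab + w_face[..., None] * ac
    closest = np.where(on_bc[..., None], b + w_edge_bc[..., None] * (c - b), closest)
    closest = np.where(on_ac[..., None], a + w_edge_ac[..., None] * ac, closest)
    closest = np.where(on_ab[..., None], a + v_edge_ab[..., None] * ab, closest)
    closest = np.where(in_c[..., None], c, closest)
    closest = np.where(in_b[..., None], b, closest)
    closest = np.where(in_a[..., None], a, closest)

    return np.linalg.norm(p - closest, axis=-1)


def align_rigid_2d(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rigid (rotation + translation, no reflection) alignment in 2D.

    Returns ``source`` mapped onto ``target`` by the least-squares rigid
    motion (Kabsch/Procrustes with determinant constraint).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (source - mu_s).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = (u * np.array([1.0, d])) @ vt
    return (source - mu_s) @ r + mu_t
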