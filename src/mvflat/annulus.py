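"""Annulus reference plane and arc-length-preserving annulus parameterization.

The annulus curve is parameterized first and stays fixed through all later
flattening steps. Its height above a reference plane becomes the ``v``
coordinate and its unrolled arc length the ``u`` coordinate, so consecutive
annulus points keep their 3D distances exactly in 2D:

    v_i = <n_a, p_i - proj(p_i, P_a)>
    u_1 = 0,   u_i = u_{i-1} + sqrt(||p_i - p_{i-1}||^2 - (v_i - v_{i-1})^2)

Two plane constructions are provided. The landmark plane passes through the
two commissure points and the barycenter of the posterior annulus arc; it
accentuates the anterior saddle horn, which matters clinically because a
flattened saddle is associated with functional mitral insufficiency. The
least-squares plane minimizes total squared orthogonal distance and tends to
average the saddle away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .model import ValveMesh

logger = logging.getLogger(__name__)


@dataclass
class AnnulusPlane:
    """Reference plane with unit normal ``normal`` through point ``origin``.

    The normal is oriented so that the mean signed height of the non-annulus
    leaflet vertices is non-positive: leaflets hang toward the ventricle, so
    the positive side is the atrial side and prolapsed tissue gets positive
    height.
    """

    origin: np.ndarray
    normal: np.ndarray
    method: str

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points to the plane, positive on the atrial side."""
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        h = self.signed_height(points)
        return np.asarray(points, dtype=float) - np.outer(np.atleast_1d(h), self.normal).reshape(np.shape(points))


@dataclass
class AnnulusParam:
    """2D annulus coordinates: one (u, v) per annulus position plus the
    duplicated closing point, so ``uv`` has shape (m + 1, 2)."""

    uv: np.ndarray
    u_total: float
    clamped: int = 0  # number of Eq.-steps where the radicand was clamped to 0


def _orient(normal: np.ndarray, mesh: ValveMesh, origin: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(normal)
    if nrm < 1e-12:
        raise DegenerateGeometryError("plane-defining points are collinear")
    normal = normal / nrm
    non_annulus = np.setdiff1d(np.arange(mesh.n_vertices), mesh.annulus)
    if len(non_annulus):
        mean_h = float(np.mean((mesh.vertices[non_annulus] - origin) @ normal))
        if mean_h > 0:
            normal = -normal
    return normal


def _posterior_arc_positions(mesh: ValveMesh) -> np.ndarray:
    """Annulus positions strictly between the commissures on the posterior side."""
    m = mesh.m
    med = mesh.commissures["medial"]
    arc1 = np.arange(1, med)
    arc2 = np.arange(med + 1, m)
    labels = mesh.leaflet_of_line

    def is_posterior(arc):
        return len(arc) > 0 and all(labels[int(l)] == "posterior" for l in arc)

    if is_posterior(arc1):
        return arc1
    if is_posterior(arc2):
        return arc2
    raise DegenerateGeometryError("no contiguous posterior annulus arc between the commissures")


def landmark_plane(mesh: ValveMesh) -> AnnulusPlane:
    """Plane through the two commissure points and the posterior-arc barycenter.

    The commissure landmarks form the natural axis of the valve; the
    barycenter of the posterior annulus (commissures excluded) pins the third
    point, since the posterior annulus usually approximates a planar layout.
    """
    lat = mesh.vertices[mesh.annulus[mesh.commissures["lateral"]]]
    med = mesh.vertices[mesh.annulus[mesh.commissures["medial"]]]
    post = _posterior_arc_positions(mesh)
    bary = mesh.vertices[mesh.annulus[post]].mean(axis=0)
    normal = np.cross(med - lat, bary - lat)
    origin = (lat + med + bary) / 3.0
    return AnnulusPlane(origin=origin, normal=_orient(normal, mesh, origin), method="landmark")


def ls_plane(mesh: ValveMesh) -> AnnulusPlane:
    """Total-least-squares plane of the annulus points.

    Minimizes the sum of squared orthogonal distances (smallest principal
    component of the centered annulus point cloud).
    """
    pts = mesh.vertices[mesh.annulus]
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12:
        raise DegenerateGeometryError("annulus points are collinear; least-squares plane undefined")
    return AnnulusPlane(origin=origin, normal=_orient(vt[2], mesh, origin), method="least_squares")


def parameterize_annulus(mesh: ValveMesh, plane: AnnulusPlane) -> AnnulusParam:
    """Unroll the annulus loop into (u, v) coordinates, preserving arc length.

    The lateral commissure opens the loop at u = 0 and the loop is closed by a
    duplicated point at ``u_total``. If an annulus edge is steeper than its
    height difference allows (numerically possible), the radicand is clamped
    to 0 and a warning is logged; u stays monotone.
    """
    pts = mesh.vertices[np.concatenate([mesh.annulus, mesh.annulus[:1]])]
    v = plane.signed_height(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    radicand = seg**2 - np.diff(v) ** 2
    clamped = int(np.sum(radicand < 0))
    if clamped:
        logger.warning(
            "parameterize_annulus: clamped %d negative radicand(s); annulus edges "
            "steeper than their height difference",
            clamped,
        )
    du = np.sqrt(np.maximum(radicand, 0.0))
    u = np.concatenate([[0.0], np.cumsum(du)])
    uv = np.column_stack([u, v])
    uv[-1, 1] = uv[0, 1]  # closing duplicate shares v with the first point
    return AnnulusParam(uv=uv, u_total=float(u[-1]), clamped=clamped)
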