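"""Parameterization quality metrics: area, angle and edge-length distortion.

Area distortion per triangle pair (3D triangle t, 2D image t-bar):

    E_A(t) = A(t)/A(t_bar) + A(t_bar)/A(t)

symmetric in shrinkage and enlargement, minimum 2 at equal areas. Angle
distortion follows the cotangent (conformal) energy:

    E_M(t) = ( cot(alpha) |a|^2 + cot(beta) |b|^2 + cot(gamma) |c|^2 ) / (2 A(t))

with a, b, c the 3D edge lengths of t and alpha, beta, gamma the interior
angles of t_bar opposite the respective edges; the minimum 2 is attained when
t and t_bar have equal angle-to-edge proportions (similar triangles). All
three magnitudes are bounded below by 2 per element.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._geometry import signed_areas_2d, triangle_areas_3d
from .errors import MetricUndefinedError
from .flatten import FlatMap, count_flipped, edge_length_energy

_MIN_ANGLE = 1e-9  # rad; smaller 2D angles make the cotangent energy unreliable


@dataclass
class DistortionReport:
    per_triangle_area: np.ndarray
    per_triangle_angle: np.ndarray
    per_vertex_edge: np.ndarray
    mean_area: float
    mean_angle: float
    mean_edge: float
    flipped: int
    areas_3d: np.ndarray
    areas_2d: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_area_distortion": self.mean_area,
                "mean_angle_distortion": self.mean_angle,
                "mean_edge_length_energy": self.mean_edge,
                "flipped_triangles": self.flipped,
                "per_triangle_area_distortion": self.per_triangle_area.tolist(),
                "per_triangle_angle_distortion": self.per_triangle_angle.tolist(),
                "per_vertex_edge_length_energy": self.per_vertex_edge.tolist(),
                "triangle_areas_3d_mm2": self.areas_3d.tolist(),
                "triangle_areas_2d_mm2": self.areas_2d.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DistortionReport":
        d = json.loads(text)
        return cls(
            per_triangle_area=np.array(d["per_triangle_area_distortion"]),
            per_triangle_angle=np.array(d["per_triangle_angle_distortion"]),
            per_vertex_edge=np.array(d["per_vertex_edge_length_energy"]),
            mean_area=d["mean_area_distortion"],
            mean_angle=d["mean_angle_distortion"],
            mean_edge=d["mean_edge_length_energy"],
            flipped=d["flipped_triangles"],
            areas_3d=np.array(d["triangle_areas_3d_mm2"]),
            areas_2d=np.array(d["triangle_areas_2d_mm2"]),
        )


def _areas(flat: FlatMap):
    a3 = triangle_areas_3d(flat.cut.cut_vertices, flat.cut.cut_triangles)
    a2 = np.abs(signed_areas_2d(flat.uv, flat.cut.cut_triangles))
    return a3, a2


def area_distortion(flat: FlatMap) -> tuple[np.ndarray, float]:
    """Per-triangle area distortion E_A and its unweighted mean."""
    a3, a2 = _areas(flat)
    bad = np.where((a2 == 0) | (a3 == 0))[0]
    if len(bad):
        raise MetricUndefinedError(f"zero-area triangle(s) {bad[:10].tolist()}; area distortion undefined")
    per = a3 / a2 + a2 / a3
    return per, float(per.mean())


def angle_distortion(flat: FlatMap) -> tuple[np.ndarray, float]:
    """Per-triangle cotangent angle distortion E_M and its unweighted mean.

    Cotangents come from exact 2D vector formulae; a 2D interior angle below
    1e-9 rad raises :class:`MetricUndefinedError` rather than being clamped,
    so degenerate layouts surface as errors instead of silent numbers.
    """
    tris = flat.cut.cut_triangles
    p = flat.cut.cut_vertices
    q = flat.uv
    a3 = triangle_areas_3d(p, tris)
    if np.any(a3 == 0):
        raise MetricUndefinedError("zero-area 3D triangle; angle distortion undefined")

    per = np.zeros(len(tris))
    for corner in range(3):
        i = tris[:, corner]
        j = tris[:, (corner + 1) % 3]
        k = tris[:, (corner + 2) % 3]
        # interior 2D angle at vertex i, opposite edge (j, k)
        e1 = q[j] - q[i]
        e2 = q[k] - q[i]
        cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        dot = np.sum(e1 * e2, axis=1)
        angles = np.arctan2(np.abs(cross), dot)
        if np.any(angles < _MIN_ANGLE):
            t = int(np.where(angles < _MIN_ANGLE)[0][0])
            raise MetricUndefinedError(
                f"2D triangle {t} has an interior angle below {_MIN_ANGLE} rad; angle distortion undefined"
            )
        cot = dot / np.abs(cross)
        opp_sq = np.sum((p[j] - p[k]) ** 2, axis=1)
        per += cot * opp_sq
    per /= 2.0 * a3
    return per, float(per.mean())


def area_distortion_pair(area_3d: float, area_2d: float) -> float:
    """E_A for a single 3D/2D triangle pair given the two areas."""
    if area_3d <= 0 or area_2d <= 0:
        raise MetricUndefinedError("triangle areas must be positive")
    return area_3d / area_2d + area_2d / area_3d


def angle_distortion_pair(tri3d: np.ndarray, tri2d: np.ndarray) -> float:
    """E_M for a single pair: 3D triangle (3, 3) and its 2D image (3, 2)."""
    tri3d = np.asarray(tri3d, dtype=float)
    tri2d = np.asarray(tri2d, dtype=float)
    area3 = 0.5 * np.linalg.norm(np.cross(tri3d[1] - tri3d[0], tri3d[2] - tri3d[0]))
    if area3 == 0:
        raise MetricUndefinedError("zero-area 3D triangle; angle distortion undefined")
    total = 0.0
    for corner in range(3):
        i, j, k = corner, (corner + 1) % 3, (corner + 2) % 3
        e1 = tri2d[j] - tri2d[i]
        e2 = tri2d[k] - tri2d[i]
        cross = e1[0] * e2[1] - e1[1] * e2[0]
        dot = float(e1 @ e2)
        if np.arctan2(abs(cross), dot) < _MIN_ANGLE:
            raise MetricUndefinedError("degenerate 2D angle; angle distortion undefined")
        total += dot / abs(cross) * float(np.sum((tri3d[j] - tri3d[k]) ** 2))
    return total / (2.0 * area3)


def distortion_report(flat: FlatMap) -> DistortionReport:
    """Assemble E_l, E_A, E_M (unweighted per-vertex / per-triangle means),
    the flip count and raw triangle areas into one report."""
    a3, a2 = _areas(flat)
    per_a, mean_a = area_distortion(flat)
    per_m, mean_m = angle_distortion(flat)
    per_l, mean_l = edge_length_energy(flat)
    return DistortionReport(
        per_triangle_area=per_a,
        per_triangle_angle=per_m,
        per_vertex_edge=per_l,
        mean_area=mean_a,
        mean_angle=mean_m,
        mean_edge=mean_l,
        flipped=count_flipped(flat),
        areas_3d=a3,
        areas_2d=a2,
    )
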