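"""Pathology Score: a scalar prolapse indicator from the paired 3D/2D valve.

For every source-mesh vertex i with signed height h_i above the annulus plane
and parameter-domain coordinate v_i, the score sums

    S_P = sum_i max(0, h_i) * |min(0, v_i)|      [mm^2]

Only tissue that lies above the annulus plane (h_i > 0) *and* below the
unrolled annulus curve in the 2D layout (v_i < 0) contributes: leaflet tissue
bulging toward the atrium scores, whereas annulus points such as the anterior
saddle horn - above the plane but at non-negative v - do not. Tissue further
from the annulus (more negative v) is weighted more strongly. The vertex with
the largest addend marks the most severe prolapse.

The raw score scales with mesh vertex density; an optional area-weighted
variant multiplies each addend by the vertex's share of leaflet surface area
(one third of each incident triangle), making scores comparable across
resolutions. Cohort values are typically normalized to a maximum of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import triangle_areas_3d
from .annulus import AnnulusPlane
from .errors import ParameterError
from .flatten import FlatMap
from .model import ValveMesh


@dataclass
class ScoreResult:
    """Raw Pathology Score, per-vertex addends and the maximizing vertex.

    ``normalized`` is filled by :func:`normalize_scores` when a cohort
    maximum is available; ``max_vertex`` is None for a score of exactly 0
    (the distinguished "no prolapse" signal, not an error).
    """

    raw: float
    addends: np.ndarray
    max_vertex: int | None
    normalized: float | None = None


def score(
    mesh: ValveMesh,
    flat: FlatMap,
    plane: AnnulusPlane,
    area_weighted: bool = False,
) -> ScoreResult:
    """Compute the Pathology Score of a flattened valve.

    The sum runs over source-mesh vertices; vertices duplicated by the
    commissure cut are counted once, through their image with the more
    negative v. With ``area_weighted`` each addend is multiplied by the
    vertex's Voronoi-free area share (sum of incident triangle areas / 3),
    giving a mesh-resolution-independent variant (off by default).
    """
    heights = plane.signed_height(mesh.vertices)
    v = flat.source_uv(reduce="min_v")[:, 1]
    addends = np.maximum(0.0, heights) * np.abs(np.minimum(0.0, v))
    if area_weighted:
        weights = np.zeros(mesh.n_vertices)
        areas = triangle_areas_3d(mesh.vertices, mesh.triangles)
        for tri, a in zip(mesh.triangles, areas):
            weights[tri] += a / 3.0
        addends = addends * weights
    raw = float(addends.sum())
    max_vertex = int(np.argmax(addends)) if raw > 0 else None
    return ScoreResult(raw=raw, addends=addends, max_vertex=max_vertex)


def max_addend_vertex(result: ScoreResult) -> int | None:
    """Source-vertex index of the largest addend (ties to the lowest index);
    None when the score is 0."""
    return result.max_vertex


def normalize_scores(raw_scores) -> list:
    """Divide each raw score by the cohort maximum (all-zero cohorts stay 0).

    Raises :class:`ParameterError` on an empty list or a negative score.
    """
    raw_scores = list(raw_scores)
    if not raw_scores:
        raise ParameterError("normalize_scores needs at least one score")
    if any(s < 0 for s in raw_scores):
        raise ParameterError("scores must be non-negative")
    top = max(raw_scores)
    if top == 0:
        return [0.0 for _ in raw_scores]
    return [float(s) / top for s in raw_scores]
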