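"""Clinical mappings on the paired 3D/2D valve representation.

* height map - signed distance of every vertex to the annulus plane (positive
  on the atrial side, so prolapsed tissue is positive);
* coaptation map - per-vertex minimum distance to the opposite leaflet's
  surface, flagged where it falls within a threshold (2 mm by default);
* Carpentier segments - the A1-A3 / P1-P3 subdivision in parameter space;
* grid addressing - spreadsheet-style cell names on a 10 mm overlay grid;
* exact bidirectional 3D <-> 2D point correspondence via shared barycentric
  coordinates.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from ._geometry import barycentric_2d, barycentric_3d, point_triangle_distances
from .errors import LocationError, ParameterError
from .flatten import FlatMap
from .annulus import AnnulusPlane
from .model import ValveMesh

_BARY_TOL = 1e-9


@dataclass
class ScalarField:
    """One scalar value per source-mesh vertex (mm, or 0/1 for flags)."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SegmentLabeling:
    """Per-vertex Carpentier segment labels plus the geometry that defined them."""

    labels: list                       # one of A1..A3 / P1..P3 per source vertex
    apex_vertex: int                   # source index of the anterior-annulus midpoint
    posterior_thresholds: tuple        # u values splitting the posterior range in thirds
    anterior_coaptation_thresholds: tuple  # u values at the free edge (f = 1)
    apex_u: float


def height_map(mesh: ValveMesh, plane: AnnulusPlane) -> ScalarField:
    """Signed distance of each vertex to the annulus plane."""
    return ScalarField(name="height", values=plane.signed_height(mesh.vertices))


def _leaflet_triangles(mesh: ValveMesh, leaflet: str) -> np.ndarray:
    """Triangles whose three vertices all belong to ``leaflet``.

    Mixed triangles bridging the two leaflets at the commissures belong to
    neither surface; otherwise a query vertex could sit inside a triangle of
    the "opposite" leaflet and report zero distance.
    """
    lov = mesh.leaflet_of_vertex()
    keep = [
        ti
        for ti, tri in enumerate(mesh.triangles)
        if all(lov.get(int(v)) == leaflet for v in tri)
    ]
    return mesh.triangles[keep] if keep else np.empty((0, 3), dtype=np.int64)


def coaptation_map(mesh: ValveMesh, threshold: float = 2.0) -> tuple[ScalarField, ScalarField]:
    """Distance of every vertex to the opposite leaflet and the coaptation flag.

    Distance is vertex-to-triangle (surface distance), not vertex-to-vertex:
    a threshold on closeness of the two surfaces would otherwise miss face
    interiors. Returns ``(distance_field, flag_field)`` with the flag 1 where
    distance <= threshold.
    """
    if threshold <= 0:
        raise ParameterError("coaptation threshold must be positive")
    lov = mesh.leaflet_of_vertex()
    distances = np.full(mesh.n_vertices, np.inf)
    for own, other in (("anterior", "posterior"), ("posterior", "anterior")):
        own_idx = np.array([v for v, lab in lov.items() if lab == own], dtype=np.int64)
        tris = _leaflet_triangles(mesh, other)
        if len(own_idx) == 0 or len(tris) == 0:
            raise ParameterError(f"leaflet {other!r} has no pure triangles; coaptation map undefined")
        d = point_triangle_distances(mesh.vertices[own_idx], mesh.vertices[tris])
        distances[own_idx] = d.min(axis=1)
    flags = (distances <= threshold).astype(float)
    return (
        ScalarField(name="coaptation_distance", values=distances),
        ScalarField(name="coaptation_flag", values=flags),
    )


def _anterior_apex(mesh: ValveMesh) -> int:
    """Annulus position of the anterior midpoint: the vertex closest to half
    the anterior arc's cumulative 3D length (ties to the lower position)."""
    m = mesh.m
    med = mesh.commissures["medial"]
    if mesh.leaflet_of_line[1] == "posterior":
        arc = list(range(med, m)) + [0]       # medial -> lateral through the anterior side
    else:
        arc = list(range(0, med + 1))
    pts = mesh.vertices[mesh.annulus[np.array([p % m for p in arc])]]
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    half = cum[-1] / 2.0
    best = int(np.argmin(np.abs(cum - half)))  # argmin takes the first (lower) on ties
    return arc[best] % m


def segment_labels(flat: FlatMap, mesh: ValveMesh) -> SegmentLabeling:
    """Carpentier A1-A3 / P1-P3 labels for every source vertex.

    Posterior leaflet: the posterior u range (lateral commissure to medial
    commissure) is split into three equal half-open intervals, P1 adjacent to
    the lateral commissure. Anterior leaflet: the three segments join at the
    anterior-annulus midpoint vertex (the "apex") and occupy equal u ranges at
    the coaptation; the boundary at depth fraction f along a line is the
    straight parameter-space blend (1 - f) * u_apex + f * u_k of the apex u
    and the coaptation threshold u_k, A1 adjacent to the lateral commissure.
    """
    m = mesh.m
    med = mesh.commissures["medial"]
    ann = flat.uv[flat.cut.cut_annulus]
    u_med = float(ann[med, 0])
    u_total = float(ann[m, 0])

    posterior_first = mesh.leaflet_of_line[1] == "posterior"
    if posterior_first:
        post_lo, post_hi = 0.0, u_med
        ant_lo, ant_hi = u_med, u_total
    else:
        ant_lo, ant_hi = 0.0, u_med
        post_lo, post_hi = u_med, u_total

    p_t1 = post_lo + (post_hi - post_lo) / 3.0
    p_t2 = post_lo + 2.0 * (post_hi - post_lo) / 3.0
    a_t1 = ant_lo + (ant_hi - ant_lo) / 3.0
    a_t2 = ant_lo + 2.0 * (ant_hi - ant_lo) / 3.0

    apex_pos = _anterior_apex(mesh)
    apex_vertex = int(mesh.annulus[apex_pos])
    # the lateral commissure belongs to the anterior arc through its closing
    # duplicate at u_total when the posterior arc comes first
    if posterior_first and apex_pos == 0:
        u_apex = float(ann[m, 0])
    else:
        u_apex = float(ann[apex_pos, 0])

    # posterior numbering starts at the lateral commissure; anterior boundary
    # thresholds nearer the lateral commissure separate A1 from A2
    if posterior_first:
        p_names_asc = ["P1", "P2", "P3"]
        a_names_asc = ["A3", "A2", "A1"]   # anterior range starts at the medial side
    else:
        a_names_asc = ["A1", "A2", "A3"]
        p_names_asc = ["P3", "P2", "P1"]

    uv_src = flat.source_uv(reduce="first")
    labels = [None] * mesh.n_vertices
    for l, line in enumerate(mesh.lines):
        leaflet = mesh.leaflet_of_line[l]
        n_l = len(line)
        for j, vid in enumerate(line):
            u = float(uv_src[int(vid), 0])
            f = j / (n_l - 1)
            if leaflet == "posterior":
                labels[int(vid)] = _classify(u, p_t1, p_t2, p_names_asc)
            else:
                th1 = (1.0 - f) * u_apex + f * a_t1
                th2 = (1.0 - f) * u_apex + f * a_t2
                if th2 - th1 < _BARY_TOL:
                    # at the apex all three boundaries coincide: center segment
                    name = a_names_asc[1] if abs(u - th1) < _BARY_TOL else (
                        a_names_asc[0] if u < th1 else a_names_asc[2]
                    )
                else:
                    name = _classify(u, th1, th2, a_names_asc)
                labels[int(vid)] = name
    return SegmentLabeling(
        labels=labels,
        apex_vertex=apex_vertex,
        posterior_thresholds=(p_t1, p_t2),
        anterior_coaptation_thresholds=(a_t1, a_t2),
        apex_u=u_apex,
    )


def _classify(u: float, t1: float, t2: float, names_ascending: list) -> str:
    if u < t1:
        return names_ascending[0]
    if u < t2:
        return names_ascending[1]
    return names_ascending[2]


def grid_cell(q, spacing: float = 10.0, v_max: float = 0.0) -> str:
    """Spreadsheet-style cell address of a 2D parameter point.

    Columns are lettered A, B, C, ... from u = 0 upward in u; rows are
    numbered 1, 2, ... downward from ``v_max`` (the top of the layout). Cells
    are half-open: [lo, hi) in u and (lo, hi] descending in v, so u exactly on
    a boundary belongs to the higher column.
    """
    if spacing <= 0:
        raise ParameterError("grid spacing must be positive")
    u, v = float(q[0]), float(q[1])
    col = int(np.floor(u / spacing))
    row = int(np.floor((v_max - v) / spacing)) + 1
    if col < 0 or row < 1:
        raise LocationError(f"point ({u}, {v}) lies outside the grid (origin u=0, top v={v_max})")
    letters = ""
    c = col
    while True:
        letters = string.ascii_uppercase[c % 26] + letters
        c = c // 26 - 1
        if c < 0:
            break
    return f"{letters}{row}"


def to_2d(mesh: ValveMesh, flat: FlatMap, point3d, triangle_index: int) -> np.ndarray:
    """Map a 3D surface point in triangle ``triangle_index`` to the parameter
    domain by reusing its barycentric coordinates in the 2D image triangle.

    Triangle indices are shared between the source and cut meshes (the cut
    only re-indexes vertices).
    """
    tri3 = mesh.vertices[mesh.triangles[triangle_index]]
    bary = barycentric_3d(np.asarray(point3d, dtype=float), tri3)
    if np.any(bary < -_BARY_TOL):
        raise LocationError(
            f"point {np.asarray(point3d).tolist()} lies outside triangle {triangle_index} "
            f"(barycentric {bary.tolist()})"
        )
    tri2 = flat.uv[flat.cut.cut_triangles[triangle_index]]
    return bary @ tri2


def to_3d(mesh: ValveMesh, flat: FlatMap, point2d) -> tuple[np.ndarray, int]:
    """Map a parameter-domain point back to the 3D surface.

    The containing 2D triangle is located by scanning triangles in index
    order (deterministic first match on edges/ties); returns the 3D point and
    the triangle index. Raises :class:`LocationError` outside the layout.
    """
    point2d = np.asarray(point2d, dtype=float)
    tris2 = flat.uv[flat.cut.cut_triangles]
    a, b, c = tris2[:, 0], tris2[:, 1], tris2[:, 2]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = ((point2d[0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (point2d[1] - a[:, 1])) / det
        w2 = ((b[:, 0] - a[:, 0]) * (point2d[1] - a[:, 1]) - (point2d[0] - a[:, 0]) * (b[:, 1] - a[:, 1])) / det
    w0 = 1.0 - w1 - w2
    inside = (det != 0) & (w0 >= -_BARY_TOL) & (w1 >= -_BARY_TOL) & (w2 >= -_BARY_TOL)
    hits = np.where(inside)[0]
    if len(hits) == 0:
        raise LocationError(f"point {point2d.tolist()} lies outside the 2D layout")
    ti = int(hits[0])
    bary = np.array([w0[ti], w1[ti], w2[ti]])
    tri3 = mesh.vertices[mesh.triangles[ti]]
    return bary @ tri3, ti
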