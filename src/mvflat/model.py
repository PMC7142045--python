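"""Annotated mitral-valve mesh model, on-disk formats, validation and the commissure cut.

A valve mesh is a triangulated band of tissue: one boundary loop is the
annulus (the insertion ring of the leaflets), the other is the free edge at
the coaptation. Per-annulus-vertex "longitude" lines run from the annulus to
the free edge and carry an anterior/posterior leaflet label. Two commissure
landmarks (lateral and medial) mark where the leaflets meet; the lateral
commissure is by convention the first annulus position and is where the band
is cut open into a topological disk before flattening.

Coordinates are millimetres throughout; all indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import triangle_areas_3d, unique_edges
from .errors import FormatError, TopologyError

LEAFLET_LABELS = ("anterior", "posterior")
_DEGENERATE_AREA = 1e-12  # mm^2


@dataclass
class ValveMesh:
    """Annotated 3D valve surface.

    Attributes
    ----------
    vertices : (N, 3) float array, mm
    triangles : (T, 3) int array of vertex indices
    annulus : (m,) int array; ordered closed annulus loop, lateral commissure first
    lines : list of m int arrays; line ``l`` starts at ``annulus[l]`` and ends
        on the free edge, ordered annulus -> coaptation
    leaflet_of_line : list of m labels, each ``"anterior"`` or ``"posterior"``
    commissures : dict with keys ``"lateral"`` (must be 0) and ``"medial"``,
        positions into the annulus ordering
    """

    vertices: np.ndarray
    triangles: np.ndarray
    annulus: np.ndarray
    lines: list
    leaflet_of_line: list
    commissures: dict
    units: str = "mm"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.annulus = np.asarray(self.annulus, dtype=np.int64)
        self.lines = [np.asarray(l, dtype=np.int64) for l in self.lines]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def m(self) -> int:
        """Number of annulus points (and longitude lines)."""
        return len(self.annulus)

    def line_of_vertex(self) -> dict:
        """Map source-vertex index -> (line index, position along line)."""
        out = {}
        for l, line in enumerate(self.lines):
            for j, vid in enumerate(line):
                out[int(vid)] = (l, j)
        return out

    def leaflet_of_vertex(self) -> dict:
        """Map source-vertex index -> leaflet label, via its longitude line."""
        lov = self.line_of_vertex()
        return {v: self.leaflet_of_line[l] for v, (l, j) in lov.items()}

    def surface_area(self) -> float:
        return float(triangle_areas_3d(self.vertices, self.triangles).sum())

    def equals(self, other: "ValveMesh") -> bool:
        """Bit-exact equality on every field."""
        return (
            np.array_equal(self.vertices, other.vertices)
            and np.array_equal(self.triangles, other.triangles)
            and np.array_equal(self.annulus, other.annulus)
            and len(self.lines) == len(other.lines)
            and all(np.array_equal(a, b) for a, b in zip(self.lines, other.lines))
            and self.leaflet_of_line == other.leaflet_of_line
            and self.commissures == other.commissures
            and self.units == other.units
        )


@dataclass
class CutValveMesh:
    """Disk-topology mesh obtained by cutting a :class:`ValveMesh` along the
    lateral-commissure longitude line.

    The cut line appears twice: once as line 0 and once as an appended
    duplicate line ``m`` (so there are ``m + 1`` cut lines). ``origin_of``
    maps every cut vertex back to its source vertex.
    """

    base: ValveMesh
    cut_vertices: np.ndarray          # (N + len(line 0), 3)
    cut_triangles: np.ndarray         # (T, 3), same triangle order as base
    origin_of: np.ndarray             # (N_cut,) source indices
    cut_lines: list = field(default_factory=list)   # m + 1 index arrays into cut_vertices
    cut_annulus: np.ndarray = None    # (m + 1,) heads of cut_lines

    @property
    def n_cut_vertices(self) -> int:
        return len(self.cut_vertices)

    def euler_characteristic(self) -> int:
        e = len(unique_edges(self.cut_triangles))
        return self.n_cut_vertices - e + len(self.cut_triangles)


# ---------------------------------------------------------------------------
# validation

def validate(mesh: ValveMesh) -> list:
    """Check every data-model invariant; return a list of violation strings.

    An empty list means the mesh is valid. Each entry names the invariant and
    the offending element so files can be fixed without a debugger.
    """
    report = []
    v, t = mesh.vertices, mesh.triangles

    if mesh.units != "mm":
        report.append(f"units: expected 'mm', got {mesh.units!r}")
    if v.ndim != 2 or v.shape[1] != 3:
        report.append(f"vertices: expected (N, 3) array, got shape {v.shape}")
        return report
    if not np.all(np.isfinite(v)):
        bad = np.where(~np.isfinite(v).all(axis=1))[0]
        report.append(f"vertices: non-finite coordinates at indices {bad[:10].tolist()}")

    n = len(v)
    if len(t):
        if t.min() < 0 or t.max() >= n:
            bad = np.where((t < 0).any(axis=1) | (t >= n).any(axis=1))[0]
            report.append(f"triangles: vertex index out of range in triangles {bad[:10].tolist()}")
        else:
            areas = triangle_areas_3d(v, t)
            bad = np.where(areas <= _DEGENERATE_AREA)[0]
            if len(bad):
                report.append(f"triangles: degenerate (area <= 1e-12 mm^2) triangles {bad[:10].tolist()}")

    m = mesh.m
    if m < 6:
        report.append(f"annulus: needs at least 6 points, got {m}")
    if len(np.unique(mesh.annulus)) != m:
        report.append("annulus: duplicate vertex indices")
    if m and (mesh.annulus.min() < 0 or mesh.annulus.max() >= n):
        report.append("annulus: vertex index out of range")

    if len(mesh.lines) != m:
        report.append(f"lines: expected {m} longitude lines (one per annulus point), got {len(mesh.lines)}")
    if len(mesh.leaflet_of_line) != len(mesh.lines):
        report.append("leaflet_of_line: length differs from number of lines")

    seen = {}
    for l, line in enumerate(mesh.lines):
        if len(line) < 2:
            report.append(f"line {l}: needs at least 2 vertices")
            continue
        if line.min() < 0 or line.max() >= n:
            report.append(f"line {l}: vertex index out of range")
            continue
        if l < m and line[0] != mesh.annulus[l]:
            report.append(f"line {l}: first vertex {line[0]} is not annulus vertex {mesh.annulus[l]}")
        for vid in line:
            if int(vid) in seen:
                report.append(f"line {l}: vertex {vid} already on line {seen[int(vid)]} (lines must be disjoint)")
                break
            seen[int(vid)] = l
        # Ordering heuristic: distance from the line's annulus vertex must not
        # decrease along the line (catches coaptation->annulus reversals).
        d = np.linalg.norm(v[line] - v[line[0]], axis=1)
        if np.any(np.diff(d) < -1e-9):
            report.append(f"line {l}: not ordered annulus->coaptation (distance from annulus vertex decreases)")

    for label in mesh.leaflet_of_line:
        if label not in LEAFLET_LABELS:
            report.append(f"leaflet_of_line: unknown label {label!r}")
            break

    lat = mesh.commissures.get("lateral")
    med = mesh.commissures.get("medial")
    if lat != 0:
        report.append(f"commissures: lateral must be annulus position 0, got {lat}")
    if med is None or not (0 < med < m):
        report.append(f"commissures: medial position {med} not in (0, {m})")
    elif len(mesh.leaflet_of_line) == m and all(lab in LEAFLET_LABELS for lab in mesh.leaflet_of_line):
        # Each leaflet forms one contiguous arc with the commissures at the boundaries.
        labs = mesh.leaflet_of_line
        transitions = [l for l in range(m) if labs[l] != labs[(l - 1) % m]]
        if sorted(transitions) != sorted({0, med}):
            report.append(
                f"leaflet_of_line: labels change at positions {transitions}, "
                f"expected exactly at the commissures [0, {med}]"
            )
    return report


def _require_valid(mesh: ValveMesh, context: str):
    problems = validate(mesh)
    if problems:
        raise FormatError(f"{context}: invalid valve mesh:\n  " + "\n  ".join(problems))


# ---------------------------------------------------------------------------
# I/O

def _to_json_dict(mesh: ValveMesh) -> dict:
    return {
        "units": mesh.units,
        "vertices": mesh.vertices.tolist(),
        "triangles": mesh.triangles.tolist(),
        "annulus": mesh.annulus.tolist(),
        "lines": [l.tolist() for l in mesh.lines],
        "leaflet_of_line": list(mesh.leaflet_of_line),
        "commissures": {k: int(x) for k, x in mesh.commissures.items()},
    }


def _from_json_dict(data: dict, origin: str) -> ValveMesh:
    required = ["units", "vertices", "triangles", "annulus", "lines", "leaflet_of_line", "commissures"]
    for key in required:
        if key not in data:
            raise FormatError(f"{origin}: missing field {key!r}")
    mesh = ValveMesh(
        vertices=np.array(data["vertices"], dtype=float),
        triangles=np.array(data["triangles"], dtype=np.int64).reshape(-1, 3),
        annulus=np.array(data["annulus"], dtype=np.int64),
        lines=[np.array(l, dtype=np.int64) for l in data["lines"]],
        leaflet_of_line=list(data["leaflet_of_line"]),
        commissures={k: int(x) for k, x in data["commissures"].items()},
        units=data["units"],
    )
    _require_valid(mesh, origin)
    return mesh


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_valve(path) -> ValveMesh:
    """Read a valve from a self-describing JSON file or OBJ/PLY + JSON sidecar.

    The sidecar of ``valve.obj`` is ``valve.json`` and carries the annotation
    fields (annulus, lines, labels, commissures, units); the OBJ/PLY carries
    geometry only. Validation runs on load; any invariant violation raises
    :class:`~mvflat.errors.FormatError` naming the offending field.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return _from_json_dict(data, str(path))
    if path.suffix.lower() in (".obj", ".ply"):
        import trimesh

        tm = trimesh.load(str(path), process=False, maintain_order=True, force="mesh")
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"{path}: annotation sidecar {sidecar} not found")
        with open(sidecar) as fh:
            data = json.load(fh)
        data = dict(data)
        data["vertices"] = np.asarray(tm.vertices, dtype=float).tolist()
        data["triangles"] = np.asarray(tm.faces, dtype=np.int64).tolist()
        return _from_json_dict(data, str(path))
    raise FormatError(f"{path}: unsupported extension {path.suffix!r} (expected .json, .obj or .ply)")


def write_valve(mesh: ValveMesh, path) -> None:
    """Write a valve to disk.

    ``.json`` writes the lossless self-describing format (bit-exact round
    trip). ``.obj``/``.ply`` write ASCII geometry plus a JSON annotation
    sidecar of the same basename; coordinates are written at full ``repr``
    precision for OBJ and binary-exact doubles are not guaranteed by every
    third-party PLY reader.
    """
    _require_valid(mesh, "write_valve")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        with open(path, "w") as fh:
            json.dump(_to_json_dict(mesh), fh)
        return
    if suffix in (".obj", ".ply"):
        if suffix == ".obj":
            with open(path, "w") as fh:
                fh.write("# mvflat valve geometry\n")
                for p in mesh.vertices:
                    fh.write(f"v {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
                for t in mesh.triangles:
                    fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
        else:
            import trimesh

            tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
            with open(path, "wb") as fh:
                fh.write(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
        annotation = _to_json_dict(mesh)
        del annotation["vertices"], annotation["triangles"]
        with open(_sidecar_path(path), "w") as fh:
            json.dump(annotation, fh)
        return
    raise FormatError(f"{path}: unsupported extension {path.suffix!r} (expected .json, .obj or .ply)")


# ---------------------------------------------------------------------------
# commissure cut

def _edge_key(i, j):
    return (i, j) if i < j else (j, i)


def cut_at_commissure(mesh: ValveMesh) -> CutValveMesh:
    """Cut the valve band open along the lateral-commissure line (line 0).

    Every vertex of line 0 is duplicated; triangles on the "wrap-around" side
    of the seam (the side adjacent to line ``m - 1``) are re-indexed to the
    duplicates. The result is a topological disk (Euler characteristic 1),
    which is required for a bijective planar parameterization of the band.
    Total surface area is unchanged.
    """
    _require_valid(mesh, "cut_at_commissure")
    seam = [int(x) for x in mesh.lines[0]]
    seam_set = set(seam)
    seam_edges = {_edge_key(a, b) for a, b in zip(seam[:-1], seam[1:])}

    tris = mesh.triangles
    incident = {s: [] for s in seam}
    for ti, tri in enumerate(tris):
        for vid in tri:
            if int(vid) in seam_set:
                incident[int(vid)].append(ti)

    # For each seam vertex, split its incident triangle fan into the two sides
    # of the seam: triangles are connected if they share a non-seam edge
    # through the vertex.
    side_b_tris = set()     # triangles that will reference duplicates
    prev_side_b = None
    for si, s in enumerate(seam):
        fan = incident[s]
        if not fan:
            raise TopologyError(f"seam vertex {s} has no incident triangles")
        adj = {ti: [] for ti in fan}
        edge_to_tri = {}
        for ti in fan:
            tri = [int(x) for x in tris[ti]]
            others = [x for x in tri if x != s]
            for o in others:
                key = _edge_key(s, o)
                if key in seam_edges:
                    continue
                edge_to_tri.setdefault(key, []).append(ti)
        for key, tlist in edge_to_tri.items():
            for a in tlist:
                for b in tlist:
                    if a != b:
                        adj[a].append(b)
        # connected components of the fan
        comps = []
        unseen = set(fan)
        while unseen:
            start = min(unseen)
            stack, comp = [start], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                unseen.discard(x)
                stack.extend(y for y in adj[x] if y not in comp)
            comps.append(comp)
        if len(comps) != 2:
            raise TopologyError(
                f"cut along line 0 does not separate the triangle fan at vertex {s} "
                f"into two sides (got {len(comps)} components); mesh is not a closed "
                "band around the annulus"
            )
        if prev_side_b is None:
            # Anchor the duplicate side at the annulus: the component containing
            # the triangle incident to the wrap-around annulus edge
            # (annulus[m-1], annulus[0]).
            wrap = _edge_key(int(mesh.annulus[-1]), int(mesh.annulus[0]))
            anchor = None
            for comp in comps:
                for ti in comp:
                    tri = {int(x) for x in tris[ti]}
                    if set(wrap) <= tri:
                        anchor = comp
                        break
                if anchor is not None:
                    break
            if anchor is None:
                raise TopologyError(
                    "no triangle spans the wrap-around annulus edge "
                    f"{wrap}; the annulus loop is not closed by the triangulation"
                )
            chosen = anchor
        else:
            shared = [comp for comp in comps if comp & prev_side_b]
            if len(shared) != 1:
                raise TopologyError(f"inconsistent seam sides at vertex {s}")
            chosen = shared[0]
        side_b_tris |= chosen
        prev_side_b = chosen

    n = mesh.n_vertices
    dup_id = {s: n + k for k, s in enumerate(seam)}
    cut_vertices = np.vstack([mesh.vertices, mesh.vertices[seam]])
    cut_triangles = tris.copy()
    for ti in side_b_tris:
        for c in range(3):
            vid = int(cut_triangles[ti, c])
            if vid in dup_id:
                cut_triangles[ti, c] = dup_id[vid]
    origin_of = np.concatenate([np.arange(n, dtype=np.int64), np.array(seam, dtype=np.int64)])

    cut_lines = [np.asarray(l, dtype=np.int64) for l in mesh.lines]
    cut_lines.append(np.array([dup_id[s] for s in seam], dtype=np.int64))
    cut_annulus = np.array([line[0] for line in cut_lines], dtype=np.int64)

    cut = CutValveMesh(
        base=mesh,
        cut_vertices=cut_vertices,
        cut_triangles=cut_triangles,
        origin_of=origin_of,
        cut_lines=cut_lines,
        cut_annulus=cut_annulus,
    )
    chi = cut.euler_characteristic()
    if chi != 1:
        raise TopologyError(f"cut mesh is not a disk (Euler characteristic {chi}, expected 1)")
    return cut
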