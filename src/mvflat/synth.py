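"""Parametric synthetic valve fixtures with ground truth.

The generator emulates the annotated-mesh structure produced by
echocardiography segmentation pipelines: an elliptic, saddle-shaped annulus
sampled at ``m`` points, ``m`` longitude lines of ``n`` vertices blending each
annulus point toward a central coaptation curve with a quadratic sag profile,
and a regular two-triangles-per-quad strip between adjacent lines.

Morphologies
------------
healthy
    All leaflet tissue strictly below the annulus plane; free edges of the two
    leaflets 1 mm apart (coapting under the 2 mm criterion).
prolapse / billowing / flail
    A separable Gaussian bump in (annulus angle, line-depth fraction) displaces
    leaflet tissue toward the atrial side. Flail is a tall narrow spike at the
    free edge (ruptured chordae), billowing a broad mid-leaflet bulge, prolapse
    an intermediate localized bulge.
functional_mi
    Flattened annulus (saddle scaled to 20 %) and a coaptation gap ``g``
    between the opposing free edges; leaflet tissue itself stays below the
    plane.
developable_strip
    An exactly developable surface (vertical generalized cylinder over the
    annulus ellipse with a gentle annulus height wave): every panel between
    adjacent lines is planar, so an exactly isometric 2D layout exists and is
    recorded as ``flat_truth``.

Default dimensions follow typical adult mitral geometry: a 31 x 25 mm annulus
ellipse, 2.5 mm saddle height and 9 mm leaflet depth below the plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .annulus import landmark_plane
from .errors import ParameterError
from .model import ValveMesh, cut_at_commissure

PATHOLOGIES = ("healthy", "prolapse", "billowing", "flail", "functional_mi", "developable_strip")

_HEALTHY_GAP = 1.0        # mm between opposing free edges of a coapting valve
_POSTERIOR_SADDLE = 0.3   # posterior saddle height relative to the anterior horn
_SHOULDER_DEPTH = 1.2     # mm below the plane for the first off-annulus row
_FUNCTIONAL_SADDLE = 0.2  # annulus flattening factor for functional MI

# Bump presets (amplitude mm, (theta_c, f_c), (sigma_theta rad, sigma_f)).
_BUMP_PRESETS = {
    "prolapse": (6.0, (math.pi / 2, 0.70), (0.45, 0.30)),
    "billowing": (6.0, (math.pi / 2, 0.55), (1.00, 0.45)),
    "flail": (12.0, (math.pi / 2, 1.00), (0.35, 0.12)),
}


@dataclass
class SyntheticValveSpec:
    """Parameters of one synthetic valve; see the module docstring for the
    morphology semantics. ``m`` must be even so the medial commissure falls on
    a sampled annulus point."""

    m: int = 32
    n: int = 8
    annulus_radii: tuple = (15.5, 12.5)
    saddle_height: float = 2.5
    leaflet_depth: float = 9.0
    pathology: str = "healthy"
    bulge_amplitude: float | None = None
    bulge_center: tuple | None = None
    bulge_width: tuple | None = None
    coaptation_gap: float = 5.0
    jitter_sd: float = 0.0
    seed: int = 0

    def resolved(self) -> "SyntheticValveSpec":
        """Fill pathology-dependent bump defaults for unset fields."""
        if self.pathology not in _BUMP_PRESETS:
            return self
        amp, center, width = _BUMP_PRESETS[self.pathology]
        return replace(
            self,
            bulge_amplitude=self.bulge_amplitude if self.bulge_amplitude is not None else amp,
            bulge_center=self.bulge_center if self.bulge_center is not None else center,
            bulge_width=self.bulge_width if self.bulge_width is not None else width,
        )

    def validate(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ParameterError(f"unknown pathology {self.pathology!r}; expected one of {PATHOLOGIES}")
        if self.m < 8 or self.m % 2:
            raise ParameterError(f"m must be even and >= 8, got {self.m}")
        if self.n < 3:
            raise ParameterError(f"n must be >= 3, got {self.n}")
        if min(self.annulus_radii) <= 0 or self.leaflet_depth <= 0:
            raise ParameterError("annulus radii and leaflet depth must be positive")
        if self.saddle_height < 0 or self.coaptation_gap < 0 or self.jitter_sd < 0:
            raise ParameterError("saddle height, coaptation gap and jitter must be non-negative")
        if self.bulge_amplitude is not None and self.bulge_amplitude < 0:
            raise ParameterError("bulge amplitude must be non-negative")
        if self.leaflet_depth <= _SHOULDER_DEPTH:
            raise ParameterError(f"leaflet depth must exceed the {_SHOULDER_DEPTH} mm shoulder depth")


@dataclass
class GroundTruth:
    """Exact per-vertex ground truth computed on the noiseless construction.

    prolapse_mask
        True for non-annulus vertices that the pathologic bump lifted above the
        landmark annulus plane (always all-False for bump-free morphologies).
    flat_truth
        Exactly isometric (u, v) layout of the cut mesh; only for
        ``developable_strip``.
    expected_score_positive
        True iff some tissue lies above the plane with negative v, i.e. the
        Pathology Score of the valve must be strictly positive.
    """

    prolapse_mask: np.ndarray
    flat_truth: np.ndarray | None
    expected_score_positive: bool


def _annulus_polyline(spec: SyntheticValveSpec):
    r_u, r_w = spec.annulus_radii
    theta = 2.0 * math.pi * np.arange(spec.m) / spec.m
    saddle = spec.saddle_height * (_FUNCTIONAL_SADDLE if spec.pathology == "functional_mi" else 1.0)
    scale = np.where(np.sin(theta) > 0, _POSTERIOR_SADDLE, 1.0)  # posterior side is y > 0
    z = saddle * np.maximum(0.0, -np.cos(2.0 * theta)) * scale
    return theta, np.column_stack([r_u * np.cos(theta), r_w * np.sin(theta), z])


def _labels_and_commissures(m: int):
    labels = ["posterior" if l < m // 2 else "anterior" for l in range(m)]
    return labels, {"lateral": 0, "medial": m // 2}


def _grid_triangles(m: int, n: int) -> np.ndarray:
    tris = []
    for l in range(m):
        l2 = (l + 1) % m
        for j in range(n - 1):
            a, b = l * n + j, l2 * n + j
            c, d = l * n + j + 1, l2 * n + j + 1
            tris.append((a, b, c))
            tris.append((b, d, c))
    return np.array(tris, dtype=np.int64)


def _circular_distance(theta: np.ndarray, center: float) -> np.ndarray:
    d = np.abs((theta - center) % (2.0 * math.pi))
    return np.minimum(d, 2.0 * math.pi - d)


def _build_curtain(spec: SyntheticValveSpec) -> ValveMesh:
    """Leaflet curtain for every morphology except the developable strip."""
    m, n = spec.m, spec.n
    theta, annulus_pts = _annulus_polyline(spec)
    labels, commissures = _labels_and_commissures(m)
    gap = spec.coaptation_gap if spec.pathology == "functional_mi" else _HEALTHY_GAP
    d = spec.leaflet_depth

    f = np.arange(n) / (n - 1)
    f1 = f[1]
    # depth below the plane for rows j >= 1: shoulder depth at the first row,
    # quadratic sag down to the full leaflet depth at the free edge
    sag = _SHOULDER_DEPTH + (d - _SHOULDER_DEPTH) * ((f - f1) / (1.0 - f1)) ** 2

    vertices = np.zeros((m * n, 3))
    for l in range(m):
        y_edge = 0.5 * gap if labels[l] == "posterior" else -0.5 * gap
        target = np.array([annulus_pts[l, 0], y_edge])
        xy = np.outer(1.0 - f, annulus_pts[l, :2]) + np.outer(f, target)
        z = np.full(n, annulus_pts[l, 2])
        z[1:] = -sag[1:]
        vertices[l * n : (l + 1) * n, :2] = xy
        vertices[l * n : (l + 1) * n, 2] = z

    if spec.pathology in _BUMP_PRESETS:
        amp = spec.bulge_amplitude
        theta_c, f_c = spec.bulge_center
        sig_t, sig_f = spec.bulge_width
        dtheta = _circular_distance(theta, theta_c)
        bump = amp * np.exp(
            -(dtheta[:, None] ** 2) / (2.0 * sig_t**2) - ((f[None, :] - f_c) ** 2) / (2.0 * sig_f**2)
        )
        bump[:, 0] = 0.0  # the annulus never moves
        vertices[:, 2] += bump.reshape(-1)

    lines = [np.arange(l * n, (l + 1) * n, dtype=np.int64) for l in range(m)]
    return ValveMesh(
        vertices=vertices,
        triangles=_grid_triangles(m, n),
        annulus=np.array([l * n for l in range(m)], dtype=np.int64),
        lines=lines,
        leaflet_of_line=labels,
        commissures=commissures,
    )


def _build_strip(spec: SyntheticValveSpec):
    """Exactly developable valve: vertical cylinder over the annulus ellipse.

    The annulus carries a gentle sin(2*theta) height wave whose symmetric
    sampling puts the commissures and the posterior barycenter at z = 0, so
    the landmark plane is z = 0 and the annulus v equals the construction
    height exactly. Every panel between adjacent vertical lines is planar, so
    unrolling panel by panel is an exact isometry; the resulting layout is
    returned as ground truth.
    """
    m, n = spec.m, spec.n
    r_u, r_w = spec.annulus_radii
    theta = 2.0 * math.pi * np.arange(m) / m
    row = spec.leaflet_depth / (n - 1)
    wave = min(spec.saddle_height, 0.5 * row)  # keep first-row tissue below the plane
    z_a = wave * np.sin(2.0 * theta)

    vertices = np.zeros((m * n, 3))
    for l in range(m):
        vertices[l * n : (l + 1) * n, 0] = r_u * math.cos(theta[l])
        vertices[l * n : (l + 1) * n, 1] = r_w * math.sin(theta[l])
        vertices[l * n : (l + 1) * n, 2] = z_a[l] - row * np.arange(n)

    labels, commissures = _labels_and_commissures(m)
    mesh = ValveMesh(
        vertices=vertices,
        triangles=_grid_triangles(m, n),
        annulus=np.array([l * n for l in range(m)], dtype=np.int64),
        lines=[np.arange(l * n, (l + 1) * n, dtype=np.int64) for l in range(m)],
        leaflet_of_line=labels,
        commissures=commissures,
    )

    # exact development: u advances by the horizontal chord between lines
    xy = np.column_stack([r_u * np.cos(theta), r_w * np.sin(theta)])
    xy_closed = np.vstack([xy, xy[:1]])
    du = np.linalg.norm(np.diff(xy_closed, axis=0), axis=1)
    u_lines = np.concatenate([[0.0], np.cumsum(du)])
    z_closed = np.concatenate([z_a, z_a[:1]])

    cut = cut_at_commissure(mesh)
    flat_truth = np.zeros((cut.n_cut_vertices, 2))
    for l, line in enumerate(cut.cut_lines):
        flat_truth[line, 0] = u_lines[l]
        flat_truth[line, 1] = z_closed[l] - row * np.arange(n)
    return mesh, flat_truth


def generate_valve(spec: SyntheticValveSpec) -> tuple[ValveMesh, GroundTruth]:
    """Build one valve and its ground truth; deterministic for a fixed seed.

    Ground-truth masks are computed on the noiseless construction; isotropic
    vertex jitter (``jitter_sd`` > 0) is applied afterwards, so the masks stay
    exact by construction.
    """
    spec.validate()
    spec = spec.resolved()

    flat_truth = None
    if spec.pathology == "developable_strip":
        mesh, flat_truth = _build_strip(spec)
    else:
        mesh = _build_curtain(spec)

    plane = landmark_plane(mesh)
    heights = plane.signed_height(mesh.vertices)
    non_annulus = np.ones(mesh.n_vertices, dtype=bool)
    non_annulus[mesh.annulus] = False

    if spec.pathology in ("healthy", "functional_mi") and np.any(heights[non_annulus] >= 0):
        raise ParameterError(
            f"{spec.pathology} construction places tissue on or above the annulus plane; "
            "reduce the saddle height or increase the leaflet depth"
        )

    if spec.pathology in _BUMP_PRESETS:
        prolapse_mask = non_annulus & (heights > 0)
    else:
        prolapse_mask = np.zeros(mesh.n_vertices, dtype=bool)

    # Tissue above the plane scores iff it sits at negative v; off-annulus
    # vertices are placed at negative v by the iso-u initialization and stay
    # there, so any above-plane tissue implies a positive score.
    expected_positive = bool(np.any(heights[non_annulus] > 0))

    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mesh.vertices = mesh.vertices + rng.normal(0.0, spec.jitter_sd, mesh.vertices.shape)

    return mesh, GroundTruth(
        prolapse_mask=prolapse_mask,
        flat_truth=flat_truth,
        expected_score_positive=expected_positive,
    )


_PATHOLOGIC = {"prolapse", "billowing", "flail"}


def generate_cohort(n_valves: int, mix: dict | None = None, seed: int = 0) -> list:
    """Reproducible cohort of synthetic valves.

    ``mix`` maps pathology names to proportions (normalized internally;
    default 50 % healthy / 50 % prolapse). Counts are assigned by largest
    remainder, the order is a seeded permutation, and each valve gets mild
    seeded variation of its global dimensions. Returns a list of
    ``(ValveMesh, GroundTruth, label)`` with label ``"p"`` for the degenerative
    morphologies (prolapse, billowing, flail) and ``"n"`` otherwise.
    """
    if n_valves < 1:
        raise ParameterError("n_valves must be >= 1")
    mix = dict(mix) if mix else {"healthy": 0.5, "prolapse": 0.5}
    for key in mix:
        if key not in PATHOLOGIES:
            raise ParameterError(f"unknown pathology {key!r} in mix")
    total = sum(mix.values())
    if total <= 0:
        raise ParameterError("mix proportions must sum to a positive value")

    names = sorted(mix)
    quotas = [mix[k] / total * n_valves for k in names]
    counts = [int(q) for q in quotas]
    remainders = sorted(range(len(names)), key=lambda i: (-(quotas[i] - counts[i]), names[i]))
    for i in remainders[: n_valves - sum(counts)]:
        counts[i] += 1

    assignment = [name for name, c in zip(names, counts) for _ in range(c)]
    rng = np.random.default_rng(seed)
    assignment = [assignment[i] for i in rng.permutation(n_valves)]

    cohort = []
    for pathology in assignment:
        r_scale = rng.uniform(0.9, 1.1)
        spec = SyntheticValveSpec(
            pathology=pathology,
            annulus_radii=(15.5 * r_scale, 12.5 * r_scale),
            leaflet_depth=9.0 * rng.uniform(0.9, 1.1),
            saddle_height=2.5 * rng.uniform(0.8, 1.2),
            bulge_amplitude=(
                _BUMP_PRESETS[pathology][0] * rng.uniform(0.8, 1.2) if pathology in _BUMP_PRESETS else None
            ),
            seed=int(rng.integers(2**31)),
        )
        mesh, truth = generate_valve(spec)
        cohort.append((mesh, truth, "p" if pathology in _PATHOLOGIC else "n"))
    return cohort
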