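"""Leaflet flattening: iso-u initialization and spring relaxation toward an
equiareal layout.

After the annulus is fixed in 2D, each longitude line is dropped straight
down from its annulus point (all points share the annulus u; consecutive
points keep their 3D distance in v). This gives a valid, flip-free layout
whose lines are parallel, but which misrepresents leaflet area. A spring
relaxation then moves the free (non-annulus) vertices: every mesh edge is a
spring whose rest length is the 3D edge length,

    F_i = sum_{j in N_i} k (||p_j - p_i|| - ||q_j - q_i||) (q_i - q_j)/||q_i - q_j||

so endpoints of a 2D edge shorter than its 3D rest length are pushed apart
(this is the negative gradient of the spring potential), with constant
stiffness k = 1, integrated by an explicit Euler scheme with a
frozen force snapshot per iteration (Jacobi update, order independent).
Angle terms are deliberately absent from the objective: area fidelity is the
priority for valve tissue and always competes with angular distortion.

The quality functional tracked per vertex is the edge-length energy

    E_l(i) = 1/|N_i| * sum_j ( ||q_i - q_j|| / ||p_i - p_j|| + ||p_i - p_j|| / ||q_i - q_j|| )

which attains its minimum E_l = 2 exactly when every incident edge is
length-preserving (AM-GM per edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._geometry import signed_areas_2d, unique_edges
from .annulus import AnnulusParam
from .errors import CoverageError, DegenerateGeometryError, DivergenceError, MetricUndefinedError
from .model import CutValveMesh

logger = logging.getLogger(__name__)


@dataclass
class FlatMap:
    """2D parameterization of a cut valve mesh: one (u, v) in mm per cut vertex."""

    uv: np.ndarray
    cut: CutValveMesh

    @property
    def triangles_2d(self) -> np.ndarray:
        return self.cut.cut_triangles

    def copy(self) -> "FlatMap":
        return FlatMap(uv=self.uv.copy(), cut=self.cut)

    def annulus_mask(self) -> np.ndarray:
        """Boolean mask over cut vertices: True for the fixed annulus heads."""
        mask = np.zeros(len(self.uv), dtype=bool)
        mask[self.cut.cut_annulus] = True
        return mask

    def source_uv(self, reduce: str = "first") -> np.ndarray:
        """Per-source-vertex (u, v).

        ``reduce='first'`` takes the first cut image of each source vertex;
        ``reduce='min_v'`` takes the image with the more negative v (used by
        the Pathology Score so the duplicated cut line is counted once, with
        its deeper image).
        """
        n = self.cut.base.n_vertices
        out = np.full((n, 2), np.nan)
        if reduce == "first":
            for ci in range(len(self.uv) - 1, -1, -1):
                out[self.cut.origin_of[ci]] = self.uv[ci]
        elif reduce == "min_v":
            for ci in range(len(self.uv)):
                si = self.cut.origin_of[ci]
                if np.isnan(out[si, 1]) or self.uv[ci, 1] < out[si, 1]:
                    out[si] = self.uv[ci]
        else:
            raise ValueError(f"unknown reduce rule {reduce!r}")
        if np.isnan(out).any():
            missing = np.where(np.isnan(out[:, 0]))[0]
            raise CoverageError(f"source vertices without parameterization: {missing[:10].tolist()}")
        return out


@dataclass
class RelaxOptions:
    """Knobs of the spring relaxation.

    stiffness : spring constant k (dimensionless with coordinates in mm)
    step : explicit-Euler step size eta
    max_iter : iteration cap
    tol : convergence threshold on the maximum per-iteration displacement;
        if None, defaults to 1e-5 times the mean 3D edge length
    adaptive : step-size control. The spring force is the negative gradient of
        the spring potential U = sum k/2 (||q_i - q_j|| - ||p_i - p_j||)^2, so
        a step that would increase U is rejected and the step size halved
        (recovering by 5 % per accepted step, never above the initial step).
        U, not the edge-length energy, is the Lyapunov function of the spring
        flow; guarding on U is what lets the iteration reach the true force
        equilibrium.
    """

    stiffness: float = 1.0
    step: float = 0.1
    max_iter: int = 20000
    tol: float | None = None
    adaptive: bool = True

    def __post_init__(self):
        if self.stiffness <= 0 or self.step <= 0 or (self.tol is not None and self.tol <= 0):
            raise ValueError("stiffness, step and tol must be positive")


@dataclass
class RelaxTrace:
    energies: list = field(default_factory=list)  # mean E_l per iteration (index 0 = initial)
    iterations: int = 0
    terminated_by: str = "converged"


def _edge_arrays(flat: FlatMap):
    edges = unique_edges(flat.cut.cut_triangles)
    p = flat.cut.cut_vertices
    rest = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
    return edges, rest


def initialize_leaflets(cut: CutValveMesh, ann: AnnulusParam) -> FlatMap:
    """Initial layout: each longitude line becomes a vertical iso-u chain.

    For line ``l`` every vertex gets the annulus u of that line, and v drops
    from the annulus value by the cumulative 3D distances along the line, so
    within-line edge lengths are preserved exactly. Requires lines ordered
    annulus -> coaptation and every cut vertex to lie on a line.
    """
    uv = np.full((cut.n_cut_vertices, 2), np.nan)
    p = cut.cut_vertices
    for l, line in enumerate(cut.cut_lines):
        u0, v0 = ann.uv[l]
        steps = np.linalg.norm(np.diff(p[line], axis=0), axis=1)
        if np.any(steps == 0):
            j = int(np.where(steps == 0)[0][0])
            raise DegenerateGeometryError(
                f"line {l}: zero-length step between positions {j} and {j + 1}"
            )
        v = v0 - np.concatenate([[0.0], np.cumsum(steps)])
        uv[line, 0] = u0
        uv[line, 1] = v
    # annulus row must equal the annulus parameterization exactly
    uv[cut.cut_annulus] = ann.uv
    if np.isnan(uv).any():
        missing = np.where(np.isnan(uv[:, 0]))[0]
        raise CoverageError(
            f"cut vertices not covered by any longitude line: {missing[:10].tolist()}"
        )
    return FlatMap(uv=uv, cut=cut)


def spring_force(flat: FlatMap, k: float = 1.0) -> np.ndarray:
    """Per-vertex summed 2D spring force (annulus forces are reported too,
    but the annulus is never moved). Springs with coincident 2D endpoints
    contribute nothing for that evaluation."""
    edges, rest = _edge_arrays(flat)
    return _spring_force_edges(flat.uv, edges, rest, k)


def _spring_force_edges(uv: np.ndarray, edges: np.ndarray, rest: np.ndarray, k: float) -> np.ndarray:
    d = uv[edges[:, 1]] - uv[edges[:, 0]]
    length = np.linalg.norm(d, axis=1)
    ok = length > 0
    if not ok.all():
        logger.warning("spring_force: %d coincident 2D edge(s) skipped", int((~ok).sum()))
    coeff = np.zeros_like(length)
    coeff[ok] = k * (rest[ok] - length[ok]) / length[ok]
    fe = coeff[:, None] * d
    force = np.zeros_like(uv)
    # Endpoints are pushed apart when the 2D edge is shorter than its 3D rest
    # length and pulled together when longer; this is exactly -grad of the
    # spring potential sum k/2 (||q_i - q_j|| - ||p_i - p_j||)^2.
    np.add.at(force, edges[:, 0], -fe)
    np.add.at(force, edges[:, 1], fe)
    return force


def edge_length_energy(flat: FlatMap) -> tuple[np.ndarray, float]:
    """Per-vertex edge-length energy E_l and its unweighted mean.

    Raises :class:`MetricUndefinedError` on a zero-length 2D or 3D edge.
    """
    edges, rest = _edge_arrays(flat)
    length = np.linalg.norm(flat.uv[edges[:, 0]] - flat.uv[edges[:, 1]], axis=1)
    bad = np.where((length == 0) | (rest == 0))[0]
    if len(bad):
        e = edges[bad[0]]
        raise MetricUndefinedError(f"zero-length edge ({e[0]}, {e[1]}); edge-length energy undefined")
    return _energy_from_lengths(flat.uv, edges, rest, length)


def _energy_from_lengths(uv, edges, rest, length):
    ratio = length / rest + rest / length
    per_vertex = np.zeros(len(uv))
    degree = np.zeros(len(uv))
    np.add.at(per_vertex, edges[:, 0], ratio)
    np.add.at(per_vertex, edges[:, 1], ratio)
    np.add.at(degree, edges[:, 0], 1.0)
    np.add.at(degree, edges[:, 1], 1.0)
    used = degree > 0
    per_vertex[used] /= degree[used]
    return per_vertex, float(per_vertex[used].mean())


def _mean_energy(uv, edges, rest):
    length = np.linalg.norm(uv[edges[:, 0]] - uv[edges[:, 1]], axis=1)
    if np.any(length == 0):
        return np.inf
    return _energy_from_lengths(uv, edges, rest, length)[1]


def spring_potential(flat: FlatMap, k: float = 1.0) -> float:
    """Total spring potential U = sum over edges of k/2 (||q_i - q_j|| - ||p_i - p_j||)^2.

    The spring force of :func:`spring_force` is exactly -grad U, so U is the
    quantity the relaxation descends; it is 0 iff the layout is edge-length
    preserving (equivalently, mean E_l = 2).
    """
    edges, rest = _edge_arrays(flat)
    return _potential(flat.uv, edges, rest, k)


def _potential(uv, edges, rest, k):
    length = np.linalg.norm(uv[edges[:, 0]] - uv[edges[:, 1]], axis=1)
    return 0.5 * k * float(np.sum((length - rest) ** 2))


def relax(flat: FlatMap, opts: RelaxOptions | None = None) -> tuple[FlatMap, RelaxTrace]:
    """Relax the free vertices under the spring forces until the maximum
    displacement per iteration falls below the tolerance.

    The annulus row is bit-identical before and after. With the adaptive flag
    the spring potential is non-increasing across accepted steps and the
    iteration converges to the same force equilibrium a generic minimizer of
    the potential finds; a mean edge-length energy beyond 10x its initial
    value raises :class:`DivergenceError`.
    """
    opts = opts or RelaxOptions()
    edges, rest = _edge_arrays(flat)
    tol = opts.tol if opts.tol is not None else 1e-5 * float(rest.mean())
    free = ~flat.annulus_mask()

    uv = flat.uv.copy()
    trace = RelaxTrace()
    energy = _mean_energy(uv, edges, rest)
    potential = _potential(uv, edges, rest, opts.stiffness)
    trace.energies.append(energy)
    initial_energy = energy
    eta = opts.step

    for it in range(opts.max_iter):
        force = _spring_force_edges(uv, edges, rest, opts.stiffness)
        force[~free] = 0.0
        step = eta * force
        max_disp = float(np.abs(step).max()) if len(step) else 0.0
        if max_disp < tol:
            trace.iterations = it
            trace.terminated_by = "converged"
            return FlatMap(uv=uv, cut=flat.cut), trace
        candidate = uv + step
        if opts.adaptive:
            new_potential = _potential(candidate, edges, rest, opts.stiffness)
            if new_potential > potential:
                eta *= 0.5
                if eta < 1e-12:
                    trace.iterations = it
                    trace.terminated_by = "converged"
                    return FlatMap(uv=uv, cut=flat.cut), trace
                continue
            potential = new_potential
            eta = min(eta * 1.05, opts.step)
        uv = candidate
        energy = _mean_energy(uv, edges, rest)
        trace.energies.append(energy)
        if not np.isfinite(energy) or energy > 10.0 * initial_energy:
            raise DivergenceError(
                f"relaxation diverged (mean E_l {energy:.3g} vs initial {initial_energy:.3g}); "
                "try a smaller step size"
            )
    trace.iterations = opts.max_iter
    trace.terminated_by = "max_iter"
    return FlatMap(uv=uv, cut=flat.cut), trace


def count_flipped(flat: FlatMap) -> int:
    """Number of 2D triangles whose signed-area sign differs from the layout
    majority (zero-area triangles count as flipped)."""
    areas = signed_areas_2d(flat.uv, flat.cut.cut_triangles)
    pos = int(np.sum(areas > 0))
    neg = int(np.sum(areas < 0))
    majority = 1.0 if pos >= neg else -1.0
    return int(np.sum(areas * majority <= 0))
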