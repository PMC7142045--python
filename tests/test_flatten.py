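"""Initialization, spring forces, relaxation and the edge-length energy."""

import numpy as np
import pytest
from scipy.optimize import minimize

import mvflat as mv
from mvflat._geometry import align_rigid_2d, unique_edges
from mvflat.errors import MetricUndefinedError
from mvflat.flatten import FlatMap, spring_potential

from conftest import run_pipeline, tiny_band_mesh


def make_cut_quad(stretch=2.0):
    """Two-triangle quad as a minimal cut mesh: two 2-vertex 'lines', the two
    top vertices fixed (annulus), the two bottom vertices free. The initial
    layout stretches the bottom row by ``stretch``."""
    vertices = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, -1], [1.0, 0, -1]])
    tris = np.array([[0, 1, 2], [1, 3, 2]])
    cut = mv.CutValveMesh(
        base=None,
        cut_vertices=vertices,
        cut_triangles=tris,
        origin_of=np.arange(4),
        cut_lines=[np.array([0, 2]), np.array([1, 3])],
        cut_annulus=np.array([0, 1]),
    )
    uv = np.array([[0.0, 0.0], [1.0, 0.0], [-0.5 * (stretch - 1), -1.0], [1.0 + 0.5 * (stretch - 1), -1.0]])
    return FlatMap(uv=uv, cut=cut)


def brute_force_energy(uv, p, edges):
    """Independent double-loop edge-length energy."""
    neigh = {}
    for i, j in edges:
        neigh.setdefault(int(i), []).append(int(j))
        neigh.setdefault(int(j), []).append(int(i))
    per = np.zeros(len(uv))
    for i, js in neigh.items():
        acc = 0.0
        for j in js:
            l2 = np.linalg.norm(uv[i] - uv[j])
            l3 = np.linalg.norm(p[i] - p[j])
            acc += l2 / l3 + l3 / l2
        per[i] = acc / len(js)
    return per, per.mean()


class TestInitialization:
    def test_line_drops_preserve_3d_distances(self, healthy_pipe):
        cut, flat0 = healthy_pipe.cut, healthy_pipe.flat0
        for line in cut.cut_lines:
            d3 = np.linalg.norm(np.diff(cut.cut_vertices[line], axis=0), axis=1)
            d2 = np.linalg.norm(np.diff(flat0.uv[line], axis=0), axis=1)
            assert np.allclose(d2, d3, atol=1e-12)

    def test_lines_share_one_u(self, healthy_pipe):
        for line in healthy_pipe.cut.cut_lines:
            u = healthy_pipe.flat0.uv[line, 0]
            assert np.all(u == u[0])

    def test_annulus_row_equals_annulus_param(self, healthy_pipe):
        assert np.array_equal(
            healthy_pipe.flat0.uv[healthy_pipe.cut.cut_annulus], healthy_pipe.ann.uv
        )

    def test_explicit_drop_arithmetic(self):
        # a line starting at (u=5, v=1) with 3D steps 1 then 2 lands at
        # (5, 0) and (5, -2)
        vertices = np.array([[0.0, 0, 0], [0.0, 0, -1], [0.0, 0, -3]])
        line = np.array([0, 1, 2])
        steps = np.linalg.norm(np.diff(vertices[line], axis=0), axis=1)
        v = 1.0 - np.concatenate([[0.0], np.cumsum(steps)])
        assert np.allclose(v, [1.0, 0.0, -2.0])

    def test_no_flips_on_healthy_fixture(self, healthy_pipe):
        assert mv.count_flipped(healthy_pipe.flat0) == 0


class TestSpringForce:
    def test_isometric_layout_has_zero_force(self, strip_pipe):
        flat_truth = FlatMap(uv=strip_pipe.truth.flat_truth, cut=strip_pipe.cut)
        f = mv.spring_force(flat_truth)
        assert np.abs(f).max() < 1e-10

    def test_single_edge_force_directed_apart(self):
        flat = make_cut_quad()
        # isolate one spring: 3D length 2, 2D length 1
        uv = np.array([[0.0, 0.0], [1.0, 0.0]])
        p = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        edges = np.array([[0, 1]])
        from mvflat.flatten import _spring_force_edges

        f = _spring_force_edges(uv, edges, np.array([2.0]), 1.0)
        assert np.allclose(f[0], [-1.0, 0.0])
        assert np.allclose(f[1], [1.0, 0.0])

    def test_uniform_scaling_closed_form(self, healthy_pipe):
        flat = healthy_pipe.flat
        edges, = (unique_edges(flat.cut.cut_triangles),)
        p = flat.cut.cut_vertices
        s = 0.7
        scaled = FlatMap(uv=flat.uv * s, cut=flat.cut)
        from mvflat.flatten import _spring_force_edges

        rest = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
        l2 = np.linalg.norm(flat.uv[edges[:, 0]] - flat.uv[edges[:, 1]], axis=1)
        # per-edge force magnitude |k (L3 - s L2)|
        d = scaled.uv[edges[:, 1]] - scaled.uv[edges[:, 0]]
        coeff = (rest - s * l2) / (s * l2)
        expected = np.abs(coeff[:, None] * d)
        per_edge = np.abs(_spring_force_edges(scaled.uv[edges].reshape(-1, 2),
                                              np.arange(2 * len(edges)).reshape(-1, 2),
                                              rest, 1.0))
        assert np.allclose(per_edge[::2], expected, atol=1e-12)


class TestRelax:
    def test_annulus_bit_identical(self, healthy_pipe):
        before = healthy_pipe.flat0.uv[healthy_pipe.cut.cut_annulus]
        after = healthy_pipe.flat.uv[healthy_pipe.cut.cut_annulus]
        assert np.array_equal(before, after)

    def test_spring_potential_decreases_on_all_fixtures(self, suite_pipes):
        for name, pipe in suite_pipes.items():
            assert spring_potential(pipe.flat) <= spring_potential(pipe.flat0) + 1e-12, name

    def test_energy_improves_on_gently_curved_fixtures(self, suite_pipes):
        # Ratio metrics improve wherever the surface is close to developable;
        # a strongly domed billowing bulge is the known exception, where the
        # equilibrium trades ratio distortion for absolute length fidelity.
        for name in ("healthy", "prolapse", "flail", "functional_mi"):
            pipe = suite_pipes[name]
            assert pipe.trace.energies[-1] < pipe.trace.energies[0], name

    def test_spring_potential_monotone_under_adaptive_steps(self, healthy_pipe):
        # re-run a short relaxation, tracking the potential directly
        flat0 = healthy_pipe.flat0
        uv_prev = flat0.uv
        pots = [spring_potential(flat0)]
        flat, _ = mv.relax(flat0, mv.RelaxOptions(max_iter=200))
        pots.append(spring_potential(flat))
        assert pots[1] <= pots[0]

    def test_isometric_layout_returned_unchanged(self, strip_pipe):
        flat_truth = FlatMap(uv=strip_pipe.truth.flat_truth.copy(), cut=strip_pipe.cut)
        relaxed, trace = mv.relax(flat_truth)
        assert trace.iterations <= 1
        assert np.array_equal(relaxed.uv, flat_truth.uv)

    def test_quad_reaches_rest_lengths(self):
        flat = make_cut_quad(stretch=2.0)
        relaxed, trace = mv.relax(flat, mv.RelaxOptions(tol=1e-9))
        edges = unique_edges(flat.cut.cut_triangles)
        p = flat.cut.cut_vertices
        l3 = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
        l2 = np.linalg.norm(relaxed.uv[edges[:, 0]] - relaxed.uv[edges[:, 1]], axis=1)
        assert np.abs(l2 - l3).max() < 1e-4

    def test_matches_generic_minimizer_on_small_mesh(self):
        """<= 12 free vertices: the relaxation equilibrium must agree with a
        general-purpose minimizer of the same spring potential."""
        pipe = run_pipeline(tiny_band_mesh())
        flat0 = pipe.flat0
        edges = unique_edges(flat0.cut.cut_triangles)
        p = flat0.cut.cut_vertices
        rest = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
        free = np.where(~flat0.annulus_mask())[0]
        assert len(free) <= 12

        def potential(x):
            uv = flat0.uv.copy()
            uv[free] = x.reshape(-1, 2)
            L = np.linalg.norm(uv[edges[:, 0]] - uv[edges[:, 1]], axis=1)
            return 0.5 * np.sum((L - rest) ** 2)

        res = minimize(potential, flat0.uv[free].ravel(), method="L-BFGS-B",
                       options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-13})
        uv_opt = flat0.uv.copy()
        uv_opt[free] = res.x.reshape(-1, 2)
        _, e_opt = mv.edge_length_energy(FlatMap(uv=uv_opt, cut=flat0.cut))
        relaxed, _ = mv.relax(flat0, mv.RelaxOptions(tol=1e-9))
        _, e_relax = mv.edge_length_energy(relaxed)
        assert abs(e_relax - e_opt) < 1e-3

    def test_strip_recovery_rmsd(self, strip_pipe):
        aligned = align_rigid_2d(strip_pipe.flat.uv, strip_pipe.truth.flat_truth)
        rmsd = float(np.sqrt(np.mean(np.sum((aligned - strip_pipe.truth.flat_truth) ** 2, axis=1))))
        assert rmsd < 0.05


class TestEnergy:
    def test_isometric_layout_is_two(self, strip_pipe):
        flat_truth = FlatMap(uv=strip_pipe.truth.flat_truth, cut=strip_pipe.cut)
        per, mean = mv.edge_length_energy(flat_truth)
        assert abs(mean - 2.0) < 1e-9
        assert np.abs(per - 2.0).max() < 1e-9

    def test_uniform_ratio_two_gives_two_point_five(self, strip_pipe):
        # doubling an isometric layout makes every edge ratio 2, so every
        # vertex energy is 2/1 + 1/2 = 2.5
        flat = FlatMap(uv=2.0 * strip_pipe.truth.flat_truth, cut=strip_pipe.cut)
        per, mean = mv.edge_length_energy(flat)
        assert np.abs(per - 2.5).max() < 1e-9
        assert abs(mean - 2.5) < 1e-9

    def test_matches_double_loop_oracle(self, healthy_pipe):
        flat = healthy_pipe.flat
        edges = unique_edges(flat.cut.cut_triangles)
        per_o, mean_o = brute_force_energy(flat.uv, flat.cut.cut_vertices, edges)
        per, mean = mv.edge_length_energy(flat)
        assert np.allclose(per, per_o, atol=1e-12)
        assert mean == pytest.approx(mean_o, abs=1e-12)

    def test_lower_bound_two(self, suite_pipes):
        for name, pipe in suite_pipes.items():
            per, mean = mv.edge_length_energy(pipe.flat)
            assert per.min() >= 2.0 - 1e-12, name
            assert mean >= 2.0 - 1e-12, name

    def test_zero_length_edge_raises(self):
        flat = make_cut_quad()
        flat.uv[3] = flat.uv[2]
        with pytest.raises(MetricUndefinedError):
            mv.edge_length_energy(flat)


class TestFlips:
    def test_constructed_flip_detected(self):
        flat = make_cut_quad(stretch=1.0)
        assert mv.count_flipped(flat) == 0
        flipped = flat.copy()
        # reflect one free vertex across the shared diagonal
        flipped.uv[3] = np.array([-1.0, 0.5])
        assert mv.count_flipped(flipped) >= 1

    def test_zero_flips_across_suite(self, suite_pipes):
        for name, pipe in suite_pipes.items():
            assert mv.count_flipped(pipe.flat0) == 0, name
            assert mv.count_flipped(pipe.flat) == 0, name
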