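"""Height map, coaptation map, Carpentier segments, grid cells, 3D<->2D."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import mvflat as mv
from mvflat.errors import LocationError
from mvflat.mappings import grid_cell


def oracle_point_triangle(p, tri):
    """Independent point-triangle distance: constrained minimization over
    barycentric coordinates."""

    def objective(x):
        s, t = x
        q = tri[0] + s * (tri[1] - tri[0]) + t * (tri[2] - tri[0])
        return np.sum((q - p) ** 2)

    res = minimize(
        objective, [1 / 3, 1 / 3], method="SLSQP",
        bounds=[(0, 1), (0, 1)],
        constraints=[{"type": "ineq", "fun": lambda x: 1 - x[0] - x[1]}],
    )
    return np.sqrt(res.fun)


def sheet_pair(gap):
    """Two parallel 4x3 leaflet sheets ``gap`` mm apart, as a valid valve."""
    m, n = 8, 3
    vertices = []
    lines = []
    # posterior sheet at y = +gap/2, anterior at y = -gap/2, lines run in -z
    for l in range(m):
        y = gap / 2 if l < 4 else -gap / 2
        x0 = [0.0, 10.0, 20.0, 30.0][l % 4] if l < 4 else [30.0, 20.0, 10.0, 0.0][l % 4]
        base = len(vertices)
        for j in range(n):
            vertices.append([x0, y, -5.0 * j])
        lines.append(np.arange(base, base + n))
    tris = []
    for l in range(m):
        l2 = (l + 1) % m
        for j in range(n - 1):
            a, b = lines[l][j], lines[l2][j]
            c, d = lines[l][j + 1], lines[l2][j + 1]
            tris.append((a, b, c))
            tris.append((b, d, c))
    return mv.ValveMesh(
        vertices=np.array(vertices, float),
        triangles=np.array(tris),
        annulus=np.array([line[0] for line in lines]),
        lines=lines,
        leaflet_of_line=["posterior"] * 4 + ["anterior"] * 4,
        commissures={"lateral": 0, "medial": 4},
    )


class TestHeightMap:
    def test_plane_vertex_is_zero(self, healthy_pipe):
        field = mv.height_map(healthy_pipe.mesh, healthy_pipe.plane)
        on_plane = healthy_pipe.plane.project(healthy_pipe.mesh.vertices[:1])
        assert abs(healthy_pipe.plane.signed_height(on_plane[0])) < 1e-12

    def test_healthy_non_annulus_negative(self, healthy_pipe):
        field = mv.height_map(healthy_pipe.mesh, healthy_pipe.plane)
        non_annulus = np.ones(healthy_pipe.mesh.n_vertices, bool)
        non_annulus[healthy_pipe.mesh.annulus] = False
        assert field.values[non_annulus].max() < 0

    def test_positive_exactly_on_prolapse_mask(self, prolapse_pipe):
        field = mv.height_map(prolapse_pipe.mesh, prolapse_pipe.plane)
        non_annulus = np.ones(prolapse_pipe.mesh.n_vertices, bool)
        non_annulus[prolapse_pipe.mesh.annulus] = False
        positive = non_annulus & (field.values > 0)
        assert np.array_equal(positive, prolapse_pipe.truth.prolapse_mask)

    def test_rigid_invariance(self, healthy_pipe):
        import copy

        mesh = healthy_pipe.mesh
        R = Rotation.random(random_state=9).as_matrix()
        moved = copy.deepcopy(mesh)
        moved.vertices = mesh.vertices @ R.T + np.array([1.0, 2.0, 3.0])
        h1 = mv.height_map(mesh, mv.landmark_plane(mesh)).values
        h2 = mv.height_map(moved, mv.landmark_plane(moved)).values
        assert np.allclose(h1, h2, atol=1e-9)


class TestCoaptation:
    def test_parallel_sheets_one_mm_all_flagged(self):
        mesh = sheet_pair(gap=1.0)
        _, flag = mv.coaptation_map(mesh, threshold=2.0)
        assert flag.values.all()

    def test_parallel_sheets_five_mm_none_flagged(self):
        mesh = sheet_pair(gap=5.0)
        dist, flag = mv.coaptation_map(mesh, threshold=2.0)
        assert not flag.values.any()
        assert dist.values.min() == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_wedge(self):
        # wedge: sheets 0.1 mm apart at x=0 opening to ~4 mm at x=30
        mesh = sheet_pair(gap=0.1)
        lov0 = mesh.leaflet_of_vertex()
        sign = np.array([1.0 if lov0[v] == "posterior" else -1.0 for v in range(mesh.n_vertices)])
        mesh.vertices[:, 1] += sign * (mesh.vertices[:, 0] / 30.0 * 2.0)
        dist, flag = mv.coaptation_map(mesh, threshold=2.0)
        lov = mesh.leaflet_of_vertex()
        from mvflat.mappings import _leaflet_triangles

        for vid in range(mesh.n_vertices):
            other = "anterior" if lov[vid] == "posterior" else "posterior"
            tris = _leaflet_triangles(mesh, other)
            d = min(
                oracle_point_triangle(mesh.vertices[vid], mesh.vertices[t]) for t in tris
            )
            assert dist.values[vid] == pytest.approx(d, abs=1e-6)

    def test_symmetry_sanity(self, healthy_pipe):
        dist, flag = mv.coaptation_map(healthy_pipe.mesh, threshold=2.0)
        # flagged vertices exist on both leaflets of a coapting valve
        lov = healthy_pipe.mesh.leaflet_of_vertex()
        flagged = {lov[v] for v in np.where(flag.values > 0)[0]}
        assert flagged == {"anterior", "posterior"}


class TestSegments:
    def test_partition_and_leaflet_consistency(self, healthy_pipe):
        seg = mv.segment_labels(healthy_pipe.flat, healthy_pipe.mesh)
        lov = healthy_pipe.mesh.leaflet_of_vertex()
        for vid, label in enumerate(seg.labels):
            assert label in {"A1", "A2", "A3", "P1", "P2", "P3"}
            assert label.startswith("A") == (lov[vid] == "anterior")

    def test_posterior_thresholds_equal_thirds(self, healthy_pipe):
        seg = mv.segment_labels(healthy_pipe.flat, healthy_pipe.mesh)
        ann = healthy_pipe.flat.uv[healthy_pipe.cut.cut_annulus]
        u_med = ann[healthy_pipe.mesh.commissures["medial"], 0]
        assert seg.posterior_thresholds[0] == pytest.approx(u_med / 3)
        assert seg.posterior_thresholds[1] == pytest.approx(2 * u_med / 3)

    def test_apex_vertex_is_a2(self, healthy_pipe):
        seg = mv.segment_labels(healthy_pipe.flat, healthy_pipe.mesh)
        assert seg.labels[seg.apex_vertex] == "A2"

    def test_matches_pointwise_oracle(self, healthy_pipe):
        mesh, flat = healthy_pipe.mesh, healthy_pipe.flat
        seg = mv.segment_labels(flat, mesh)
        ann = flat.uv[healthy_pipe.cut.cut_annulus]
        u_med = float(ann[mesh.commissures["medial"], 0])
        u_tot = float(ann[mesh.m, 0])
        uv_src = flat.source_uv(reduce="first")
        for l, line in enumerate(mesh.lines):
            for j, vid in enumerate(line):
                u = uv_src[int(vid), 0]
                f = j / (len(line) - 1)
                if mesh.leaflet_of_line[l] == "posterior":
                    expect = "P1" if u < u_med / 3 else ("P2" if u < 2 * u_med / 3 else "P3")
                else:
                    a1 = u_med + (u_tot - u_med) / 3
                    a2 = u_med + 2 * (u_tot - u_med) / 3
                    t1 = (1 - f) * seg.apex_u + f * a1
                    t2 = (1 - f) * seg.apex_u + f * a2
                    if t2 - t1 < 1e-9:
                        expect = "A2" if abs(u - t1) < 1e-9 else ("A3" if u < t1 else "A1")
                    else:
                        expect = "A3" if u < t1 else ("A2" if u < t2 else "A1")
                assert seg.labels[int(vid)] == expect, (l, j)


class TestGrid:
    @pytest.mark.parametrize(
        "q, expect",
        [((0.1, -0.1), "A1"), ((35.0, -12.0), "D2"), ((10.0, -0.1), "B1"), ((0.0, 0.0), "A1")],
    )
    def test_examples(self, q, expect):
        assert grid_cell(q, spacing=10.0, v_max=0.0) == expect

    @given(st.floats(0, 500), st.floats(-500, 0))
    def test_floor_arithmetic(self, u, v):
        cell = grid_cell((u, v), spacing=10.0, v_max=0.0)
        row = int("".join(ch for ch in cell if ch.isdigit()))
        assert row == int(np.floor(-v / 10.0)) + 1

    def test_outside_grid_raises(self):
        with pytest.raises(LocationError):
            grid_cell((-1.0, -5.0), spacing=10.0, v_max=0.0)


class TestCorrespondence:
    def test_vertex_maps_to_own_uv(self, healthy_pipe):
        mesh, flat = healthy_pipe.mesh, healthy_pipe.flat
        ti = 10
        vid = mesh.triangles[ti][0]
        q = mv.to_2d(mesh, flat, mesh.vertices[vid], ti)
        cid = flat.cut.cut_triangles[ti][0]
        assert np.allclose(q, flat.uv[cid], atol=1e-9)

    def test_centroid_maps_to_centroid(self, healthy_pipe):
        mesh, flat = healthy_pipe.mesh, healthy_pipe.flat
        ti = 25
        c3 = mesh.vertices[mesh.triangles[ti]].mean(axis=0)
        q = mv.to_2d(mesh, flat, c3, ti)
        assert np.allclose(q, flat.uv[flat.cut.cut_triangles[ti]].mean(axis=0), atol=1e-9)

    def test_round_trip_identity(self, healthy_pipe):
        mesh, flat = healthy_pipe.mesh, healthy_pipe.flat
        rng = np.random.default_rng(1)
        for _ in range(300):
            ti = int(rng.integers(len(mesh.triangles)))
            bary = rng.dirichlet([1.0, 1.0, 1.0])
            p3 = bary @ mesh.vertices[mesh.triangles[ti]]
            q = mv.to_2d(mesh, flat, p3, ti)
            p3b, _ = mv.to_3d(mesh, flat, q)
            assert np.linalg.norm(p3 - p3b) < 1e-9

    def test_point_outside_triangle_raises(self, healthy_pipe):
        mesh, flat = healthy_pipe.mesh, healthy_pipe.flat
        far = mesh.vertices[mesh.triangles[0]].mean(axis=0) + np.array([100.0, 0, 0])
        with pytest.raises(LocationError):
            mv.to_2d(mesh, flat, far, 0)

    def test_point_outside_layout_raises(self, healthy_pipe):
        with pytest.raises(LocationError):
            mv.to_3d(healthy_pipe.mesh, healthy_pipe.flat, (1e6, 1e6))
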