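"""Shared fixtures: synthetic valves and their full flattening pipelines.

Pipelines are session-scoped; tests must not mutate the returned objects.
"""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import mvflat as mv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@dataclass
class Pipeline:
    mesh: mv.ValveMesh
    truth: mv.GroundTruth
    plane: mv.AnnulusPlane
    ann: mv.AnnulusParam
    cut: mv.CutValveMesh
    flat0: mv.FlatMap       # initialization
    flat: mv.FlatMap        # relaxed
    trace: mv.RelaxTrace


def run_pipeline(mesh, truth=None, opts=None) -> Pipeline:
    plane = mv.landmark_plane(mesh)
    ann = mv.parameterize_annulus(mesh, plane)
    cut = mv.cut_at_commissure(mesh)
    flat0 = mv.initialize_leaflets(cut, ann)
    flat, trace = mv.relax(flat0, opts)
    return Pipeline(mesh, truth, plane, ann, cut, flat0, flat, trace)


def make_pipeline(pathology: str, seed: int, **kwargs) -> Pipeline:
    mesh, truth = mv.generate_valve(mv.SyntheticValveSpec(pathology=pathology, seed=seed, **kwargs))
    return run_pipeline(mesh, truth)


@pytest.fixture(scope="session")
def healthy_pipe() -> Pipeline:
    return make_pipeline("healthy", seed=7)


@pytest.fixture(scope="session")
def prolapse_pipe() -> Pipeline:
    return make_pipeline("prolapse", seed=7)


@pytest.fixture(scope="session")
def strip_pipe() -> Pipeline:
    return make_pipeline("developable_strip", seed=1)


@pytest.fixture(scope="session")
def small_healthy() -> mv.ValveMesh:
    """Small, fast mesh for I/O and validation tests."""
    mesh, _ = mv.generate_valve(mv.SyntheticValveSpec(m=16, n=5, seed=3))
    return mesh


@pytest.fixture(scope="session")
def suite_pipes() -> dict:
    """One pipeline per pathology at default sizes (the synthetic suite)."""
    return {p: make_pipeline(p, seed=11) for p in mv.synth.PATHOLOGIES}


def tiny_band_mesh():
    """Smallest valid valve band: hexagonal annulus, one free-edge row
    (m = 6 lines of 2 vertices, 7 free vertices after the cut)."""
    m = 6
    theta = 2 * np.pi * np.arange(m) / m
    top = np.column_stack([10 * np.cos(theta), 8 * np.sin(theta), 0.4 * np.sin(2 * theta)])
    bottom = np.column_stack([6 * np.cos(theta), 4 * np.sin(theta), np.full(m, -5.0)])
    vertices = np.vstack([top, bottom])
    tris = []
    for l in range(m):
        l2 = (l + 1) % m
        tris.append((l, l2, m + l))
        tris.append((l2, m + l2, m + l))
    return mv.ValveMesh(
        vertices=vertices,
        triangles=np.array(tris),
        annulus=np.arange(m),
        lines=[np.array([l, m + l]) for l in range(m)],
        leaflet_of_line=["posterior"] * 3 + ["anterior"] * 3,
        commissures={"lateral": 0, "medial": 3},
    )
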