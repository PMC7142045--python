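"""Static 2D rendering of a flattened valve with color mappings and overlays.

Renders the parameter-domain triangulation filled by a per-vertex scalar
field: the height map uses a diverging scale centered at 0 mm (above/below the
annulus plane), the coaptation flag a binary scale. Optional overlays: the
10 mm grid with spreadsheet-style A, B, C / 1, 2, 3 cell labels, and the
Carpentier segment boundaries. Output is deterministic (fixed SVG hash salt,
no timestamps) so reruns are bit-identical.
"""

from __future__ import annotations

import string

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import matplotlib.tri as mtri
import numpy as np

from .errors import ParameterError
from .flatten import FlatMap
from .mappings import SegmentLabeling, ScalarField


def render_flatmap(
    flat: FlatMap,
    field: ScalarField | None = None,
    grid_spacing: float | None = None,
    segments: SegmentLabeling | None = None,
    title: str | None = None,
):
    """Build the matplotlib figure for a flattened valve; returns the figure."""
    plt.rcParams["svg.hashsalt"] = "mvflat"
    fig, ax = plt.subplots(figsize=(8, 5))
    tri = mtri.Triangulation(flat.uv[:, 0], flat.uv[:, 1], flat.cut.cut_triangles)

    if field is not None:
        values = _cut_values(flat, field)
        if field.name == "coaptation_flag":
            tpc = ax.tripcolor(tri, values, cmap="Greys", vmin=0.0, vmax=1.0, shading="gouraud")
            fig.colorbar(tpc, ax=ax, label="coaptation flag", ticks=[0, 1])
        else:
            vmax = float(np.max(np.abs(values))) or 1.0
            tpc = ax.tripcolor(tri, values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="gouraud")
            fig.colorbar(tpc, ax=ax, label=f"{field.name} (mm)")
    else:
        ax.triplot(tri, lw=0.4, color="0.4")

    if grid_spacing is not None:
        _draw_grid(ax, flat, grid_spacing)
    if segments is not None:
        _draw_segments(ax, flat, segments)

    ax.set_aspect("equal")
    ax.set_xlabel("u (mm)")
    ax.set_ylabel("v (mm)")
    if title:
        ax.set_title(title)
    return fig


def _cut_values(flat: FlatMap, field: ScalarField) -> np.ndarray:
    values = np.asarray(field.values, dtype=float)
    if len(values) == len(flat.uv):
        return values
    if len(values) == flat.cut.base.n_vertices:
        return values[flat.cut.origin_of]
    raise ParameterError(
        f"field {field.name!r} has {len(values)} values; expected one per source "
        f"({flat.cut.base.n_vertices}) or per cut ({len(flat.uv)}) vertex"
    )


def _column_letters(col: int) -> str:
    letters = ""
    while True:
        letters = string.ascii_uppercase[col % 26] + letters
        col = col // 26 - 1
        if col < 0:
            break
    return letters


def _draw_grid(ax, flat: FlatMap, spacing: float):
    u_min, v_min = flat.uv.min(axis=0)
    u_max, v_max = flat.uv.max(axis=0)
    u_edges = np.arange(0.0, u_max + spacing, spacing)
    v_edges = v_max - np.arange(0.0, (v_max - v_min) + spacing, spacing)
    for u in u_edges:
        ax.axvline(u, color="0.6", lw=0.5, zorder=3)
    for v in v_edges:
        ax.axhline(v, color="0.6", lw=0.5, zorder=3)
    for ci in range(len(u_edges) - 1):
        ax.text((u_edges[ci] + u_edges[ci + 1]) / 2, v_edges[0] + 0.25 * spacing,
                _column_letters(ci), ha="center", va="bottom", fontsize=8, color="0.3")
    for ri in range(len(v_edges) - 1):
        ax.text(u_edges[0] - 0.25 * spacing, (v_edges[ri] + v_edges[ri + 1]) / 2,
                str(ri + 1), ha="right", va="center", fontsize=8, color="0.3")


def _draw_segments(ax, flat: FlatMap, segments: SegmentLabeling):
    """Boundary polylines between Carpentier segments in parameter space."""
    v_min = float(flat.uv[:, 1].min())
    for t in segments.posterior_thresholds:
        ax.plot([t, t], [0.0, v_min], color="k", lw=0.8, ls="--", zorder=4)
    f = np.linspace(0.0, 1.0, 20)
    v_span = v_min * f
    for u_k in segments.anterior_coaptation_thresholds:
        u_line = (1.0 - f) * segments.apex_u + f * u_k
        ax.plot(u_line, v_span, color="k", lw=0.8, ls="--", zorder=4)


def save_figure(fig, path_png, path_svg=None) -> None:
    """Write PNG (and optionally SVG) deterministically: metadata that would
    embed timestamps or library versions is stripped."""
    fig.savefig(path_png, dpi=150, metadata={"Software": None})
    if path_svg is not None:
        fig.savefig(path_svg, metadata={"Date": None})
    plt.close(fig)
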