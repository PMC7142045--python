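# mvflat

Flattening, distortion quantification and pathology scoring for annotated
mitral-valve surface meshes.

## The problem

Patient-specific mitral-valve surface models segmented from 3D
echocardiography are convoluted, self-occluding surfaces: assessing where the
leaflets prolapse, bilge or fail to coapt requires constant 3D scene
interaction. `mvflat` unfolds such a valve into a 2D map that a clinician can
read in one gaze — the valve is cut open along the lateral commissure and
unrolled along its diameter, the way anatomy textbooks draw it — while
preserving annulus arc length exactly and leaflet areas as far as the geometry
allows. On the paired 3D/2D representation the package computes clinical
mappings (height above the annulus plane, coaptation zone, Carpentier
A1–A3/P1–P3 segments, a 10 mm measuring grid) and a scalar *Pathology Score*
that separates prolapsed from normal morphologies.

It is a library plus a `mvflat` command-line tool, and ships a parametric
synthetic-valve generator (healthy, prolapse, billowing, flail, functional
mitral insufficiency, and an exactly developable reference shape with known
ground truth), so the entire pipeline is testable without patient data.

## Method

An annotated valve consists of vertices `p_i` (mm), triangles, an ordered
annulus loop `V_a` (lateral commissure first), and per-annulus-vertex
longitude lines running annulus → free edge with an anterior/posterior label.
Flattening maps each `p_i` to `q_i = (u_i, v_i)` in three steps:

1. **Annulus parameterization.** A reference plane `P_a` (normal `n_a`) is
   fitted through the two commissure landmarks and the barycenter of the
   posterior annulus arc (a least-squares plane is available as an
   alternative). Then

       v_i = ⟨n_a, p_i − proj(p_i, P_a)⟩
       u_1 = 0,  u_i = u_{i−1} + √(‖p_i − p_{i−1}‖² − (v_i − v_{i−1})²)

   so consecutive annulus points keep their 3D distances exactly in 2D. The
   annulus stays fixed from here on.

2. **Leaflet initialization.** Each longitude line drops straight down from
   its annulus point: shared `u`, and `v` decreasing by the 3D distances along
   the line — a valid, flip-free starting layout.

3. **Spring relaxation.** Every mesh edge becomes a spring with rest length
   equal to its 3D length (stiffness k = 1); free vertices follow the summed
   spring force under an explicit Euler scheme with adaptive step control
   until equilibrium. This drives the layout toward an equiareal map; angle
   distortion is deliberately not optimized.

Quality is measured per element by the edge-length energy `E_l`, the area
distortion `E_A(t) = A(t)/A(t̄) + A(t̄)/A(t)` and the cotangent angle
distortion `E_M`; each has minimum 2, attained at length-/area-preservation
and similarity respectively.

The **Pathology Score** sums, over vertices above the annulus plane that lie
below the annulus curve in the 2D map,

    S_P = Σ_i max(0, ⟨n_a, p_i − proj(p_i, P_a)⟩) · |min(0, v_i)|   [mm²]

so atrial-side bulging tissue scores, weighted by its depth in the map, while
the naturally elevated anterior saddle horn (at v ≥ 0) does not. The largest
addend marks the most severe prolapse point.

## Worked example

```
$ mvflat synth --pathology prolapse --seed 7 -o valve.json
wrote valve.json (256 vertices, pathology=prolapse, seed=7)

$ mvflat flatten valve.json --out-dir out
flattened valve.json: E_l=2.0362 E_A=2.1136 E_M=2.2557 flips=0 (2044 iterations, converged)

$ mvflat score valve.json
valve.json: S_P=80.4422 mm^2 (normalized 1.0000, max vertex 68)
```

The flatten step reports the post-relaxation means: edge lengths are within
~1.8 % of length preservation (`E_l` = 2 would be exact), areas within ~5.7 %,
and the angle distortion is larger because it is not part of the objective;
no triangle flipped, so the map is bijective. The prolapsed valve scores
`S_P = 80.4 mm²` (a healthy valve scores exactly 0) and vertex 68 — inside the
synthetic bulge — is the most severe prolapse point. `out/` contains the
per-vertex `(u, v)` map as CSV/JSON, the distortion report, the energy trace
and a run log with input/config hashes. `mvflat render valve.json -o valve.png`
draws the 2D map with a height color map and the 10 mm grid;
`mvflat map valve.json --field coaptation -o coapt.csv` exports the
coaptation distances/flags.

## Layout

- `src/mvflat/model.py` — valve data model, JSON/OBJ/PLY I/O, validation, commissure cut
- `src/mvflat/annulus.py` — reference planes and annulus parameterization
- `src/mvflat/flatten.py` — leaflet initialization and spring relaxation
- `src/mvflat/distortion.py` — E_l / E_A / E_M metrics and reports
- `src/mvflat/mappings.py` — height map, coaptation, Carpentier segments, grid, 3D↔2D
- `src/mvflat/score.py` — Pathology Score
- `src/mvflat/synth.py` — synthetic valve generator with ground truth
- `src/mvflat/cli.py`, `src/mvflat/render.py` — command line and 2D rendering

See `docs/methods.md` for modeling assumptions, parameter defaults and known
limitations.
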