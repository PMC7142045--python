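# Methods

This note documents the models, numerical choices and limitations behind
`mvflat`, in the spirit of a methods appendix: what the code assumes, which
knobs matter, and what the tests do and do not establish.

## Data model and assumptions

A valve mesh is a triangulated **band**: one boundary loop is the annulus
(ordered, lateral commissure at position 0), the other the free edge. Each
annulus vertex heads a longitude line ordered annulus → free edge, and each
line carries an anterior/posterior label; the two label sets form contiguous
arcs meeting at the commissures. All coordinates are millimetres, all indices
0-based. Chordae tendineae and papillary muscles are not represented —
echocardiographic segmentations do not capture them reliably.

The canonical on-disk format is a self-describing JSON file (lossless,
bit-exact round trip). OBJ (+ JSON annotation sidecar) round-trips bit-exactly
too, because coordinates are written at full `repr` precision; PLY export goes
through trimesh's ASCII writer and is only guaranteed to preserve counts and
~1e-6 coordinate accuracy, so PLY is for interoperability, not archival.

One shared vertex set carries both leaflets, with leaflet membership attached
to the longitude lines; triangles that bridge the leaflets at the commissures
belong to neither leaflet surface.

### The commissure cut

Flattening a band bijectively requires disk topology, so the mesh is cut along
the lateral-commissure line: every vertex of line 0 is duplicated and the
triangle fan around each seam vertex is split into its two sides by
connectivity (two components must result, otherwise the mesh is not a closed
band and a topology error is raised). The side adjacent to the last annulus
line receives the duplicates. The cut preserves surface area exactly and the
result always has Euler characteristic 1. Both copies of the cut line are free
during relaxation except for their annulus heads — the cut is an open boundary
of the parameter domain.

## Annulus plane and parameterization

Two plane fits are provided. The **landmark plane** passes through the two
commissure landmarks and the barycenter of the posterior annulus arc
(commissures excluded — "posterior annulus" is read literally as the arc
strictly between the commissures). It accentuates the anterior saddle horn,
whose height is diagnostically relevant (a flattened saddle accompanies
functional mitral insufficiency). The **least-squares plane** is the total
least-squares fit (smallest principal component); it has minimal residual by
construction but tends to average the saddle away, which is why landmark is
the default.

The normal's sign is not fixed by three points; it is oriented so the mean
signed height of the non-annulus vertices is ≤ 0. Leaflets hang toward the
ventricle, so the positive side is the atrial side and prolapsed tissue gets
positive height — matching the height map's color convention and making the
Pathology Score's `max(0, height)` select atrial-side tissue.

The unrolling step `u_i = u_{i−1} + √(‖Δp‖² − Δv²)` is undefined when an
annulus edge is steeper than its in-plane extent; the radicand is clamped to 0
(keeping `u` monotone) and the event is counted and logged. On all shipped
fixtures the clamp never fires.

## Leaflet initialization and spring relaxation

Initialization maps each line to a vertical iso-u chain, preserving within-line
distances exactly. This requires every vertex to lie on some line (the
generator guarantees it; other meshes raise a coverage error) and gives a
flip-free layout for curtain-like geometries.

Relaxation models every mesh edge as a spring at rest at its 3D length. The
per-vertex force (stiffness k = 1, coordinates in mm)

    F_i = Σ_{j∈N_i} k (‖p_j − p_i‖ − ‖q_j − q_i‖) (q_i − q_j)/‖q_i − q_j‖

pushes the endpoints of a 2D-short edge apart and pulls a 2D-long edge
together; it is exactly −∇U of the spring potential
U = Σ_edges k/2 (‖q_i − q_j‖ − ‖p_i − p_j‖)². Free vertices are updated by
explicit Euler with a frozen force snapshot per iteration (Jacobi style, so the
result is independent of vertex order); annulus vertices never move. Springs
whose 2D endpoints coincide contribute nothing for that evaluation (logged).

Step control: the default step η = 0.1 is halved whenever a step would
increase U (the step is rejected) and recovers by 5 % per accepted step, never
exceeding the initial η. U — not the edge-length energy — is the Lyapunov
function of the spring flow; guarding on U lets the iteration reach the true
force equilibrium, and on meshes small enough to check (≤ 12 free vertices)
the final layout agrees with a quasi-Newton minimizer of the same potential to
better than 1e-3 in mean E_l. Convergence is declared when the maximum
per-iteration displacement falls below τ = 1e-5 × mean 3D edge length
(override via `RelaxOptions.tol`); the cap is 20 000 iterations. A mean E_l
exceeding 10× its initial value raises a divergence error suggesting a smaller
step.

Angle terms are deliberately absent from the objective: area fidelity is the
clinical priority (leaflet size and stretch quantification) and always
competes with angular distortion.

**A known subtlety:** the equilibrium minimizes *absolute* length deviations,
while E_l and E_A are *ratio* metrics. On gently curved valves relaxation
improves both (healthy fixture: E_l 2.11 → 2.04, E_A 2.21 → 2.10). On the
strongly domed billowing fixture the equilibrium trades ratio distortion for
length fidelity and E_l/E_A end slightly above their initialization values
(2.10 → 2.13 / 2.25 → 2.42) even though the potential drops by a factor of
four. Energy decrease is therefore an empirical property of moderately curved
inputs, not an invariant of the method.

## Distortion metrics

E_A and E_M follow the standard symmetric-ratio and cotangent (conformal)
forms; E_l, E_A, E_M are each bounded below by 2 per element (AM–GM for the
ratio forms), with equality at length preservation, equal area and similarity
respectively. Means are unweighted — per vertex for E_l, per triangle for E_A
and E_M; area-weighted averages are out of scope. Cotangents are computed from
exact 2D vector formulae; an interior 2D angle below 1e-9 rad raises an error
rather than being clamped, so degenerate layouts surface instead of producing
silent numbers.

## Mappings

- **Height map:** signed distance to the annulus plane, positive atrial-side.
- **Coaptation map:** per-vertex minimum distance to the *opposite* leaflet's
  surface, flagged within 2 mm (default). Distance is vertex-to-triangle: a
  vertex-to-vertex criterion would miss close face interiors. Only triangles
  whose three vertices belong to one leaflet count as that leaflet's surface;
  mixed commissure-bridging triangles would otherwise put a query vertex at
  zero distance from the "opposite" side. Distances are computed with a
  vectorized exact closest-point-on-triangle kernel (the meshes involved are
  small enough that the dense vertex × triangle evaluation is cheap).
- **Carpentier segments:** the posterior u-range (commissure to commissure) is
  split into three equal half-open intervals (P1 adjacent to the lateral
  commissure, the Carpentier convention). The anterior segments join at the
  annulus vertex nearest half the anterior arc's cumulative length (ties to
  the lower position) and occupy equal u-ranges at the free edge; between apex
  and free edge the boundary at line-depth fraction f is the linear blend
  (1−f)·u_apex + f·u_k. Interpolating in depth fraction rather than raw v
  keeps the rule well defined for lines of unequal length; the boundary shape
  between apex and coaptation is an implementation choice.
- **Grid:** spreadsheet-style addressing, columns A, B, C… from u = 0, rows
  1, 2… downward from the layout's maximum v, 10 mm cells, half-open.
- **3D ↔ 2D correspondence:** shared barycentric coordinates per triangle
  (the cut only re-indexes vertices, so triangle indices coincide);
  point-in-layout location scans triangles in index order for determinism on
  edges and ties.

## Pathology Score

The score's inner product uses the annulus-plane normal for every vertex
(consistent with "signed distance to the annulus plane"; a per-vertex-normal
reading would make the score depend on local tessellation). The sum runs over
source vertices; vertices duplicated by the cut contribute once, through their
image with the more negative v. The raw score scales with vertex density;
`area_weighted=True` multiplies each addend by the vertex's one-third share of
incident triangle area for a resolution-robust variant (off by default, as the
plain sum is the reference definition). Cohort normalization divides by the
cohort maximum; an all-zero cohort stays zero.

## Synthetic valves

The generator emulates the structure and the characteristic morphologies of
segmented valves, not any specific patient cohort. Defaults follow typical
adult mitral dimensions: a 31 × 25 mm annulus ellipse, 2.5 mm anterior saddle
height (posterior scaled to 30 %), 9 mm leaflet depth, m = 32 annulus points,
n = 8 vertices per line. Lines blend their annulus point toward a central
coaptation curve with a quadratic sag profile dropping from a 1.2 mm shoulder
to the full leaflet depth; healthy free edges sit 1 mm apart (coapting under
the 2 mm criterion), functional MI opens a 5 mm gap and flattens the saddle to
20 %. Pathologic displacement is a separable Gaussian bump in (annulus angle,
depth fraction) along the atrial direction: prolapse is an intermediate
localized bulge (6 mm, σ_θ = 0.45 rad, centered at depth fraction 0.7),
billowing a broad mid-leaflet dome (6 mm, σ_θ = 1.0, f_c = 0.55), flail a tall
narrow spike at the free edge (12 mm, σ_f = 0.12, f_c = 1.0 — large enough to
carry the free edge above the plane, as ruptured chordae do). m must be even
so the medial commissure falls on a sampled point.

Ground truth is computed on the noiseless construction (isotropic jitter, if
requested, is added afterwards): the prolapse mask is the bulge-displaced
tissue above the landmark plane, and `expected_score_positive` is true iff any
non-annulus tissue lies above the plane (such tissue always has v < 0 here).

The `developable_strip` morphology is a vertical generalized cylinder over the
annulus ellipse with a gentle sin 2θ annulus-height wave (symmetric sampling
puts the commissures and the posterior barycenter exactly at height 0, so the
landmark plane is the construction plane). Every panel between adjacent
vertical lines is planar, so unrolling panel by panel is an exact isometry,
recorded per cut vertex as `flat_truth`. A consequence worth stating: any
exactly isometric layout whose annulus is pinned to the arc-length
parameterization forces vertical iso-u lines, which is precisely the
initialization — so the strip verifies exactness (init ≡ ground truth, E_l = 2,
zero-iteration relaxation, sub-nanometre recovery RMSD) rather than
relaxation strength. Relaxation quality is instead exercised on the curved
healthy cohort and the small-mesh oracle comparisons. The strip's wave
amplitude is capped at half the row height so the default strip carries no
above-plane tissue and scores 0.

Cohorts (`generate_cohort`) assign pathology counts by largest remainder,
shuffle deterministically, and give each valve mild seeded variation (±10 %
radii and depth, ±20 % saddle and bulge amplitude). Labels are "p" for the
degenerative morphologies (prolapse, billowing, flail) and "n" otherwise.

What passing tests on these fixtures does **not** show: robustness to
segmentation noise and topology defects of real TEE-derived meshes, irregular
triangulations, multi-scallop prolapse, or calcified/restricted leaflets. The
generator's regular two-triangles-per-quad strips are friendlier to the spring
relaxation than real segmentations.

## Problem sizes and determinism

Default fixtures are m = 32, n = 8 (264 cut vertices); the relaxation-quality
check averages 10 such healthy valves, and oracle comparisons use a 6-line
band with 7 free vertices — sizes chosen so the full suite runs in well under
a minute while still exercising every code path. All randomness flows through
explicit seeds (`numpy.random.default_rng`); CLI outputs are byte-reproducible
(fixed SVG hash salt, no timestamps in figure metadata, `repr`-precision CSV).

## Known limitations

- The 2D layout is guaranteed flip-free empirically (checked on every
  fixture), not by construction; pathologically folded inputs could flip.
- The spring equilibrium is a local minimum reached from the iso-u
  initialization; no global optimality claim is made.
- Segment boundaries on the anterior leaflet are a modeling convention
  (linear in depth fraction); clinical segment definitions vary.
- The Pathology Score is a morphology indicator, not a classifier: it does not
  distinguish flail from billowing, and its raw value depends on mesh density
  unless the area-weighted variant is used.
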