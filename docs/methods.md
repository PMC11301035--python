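# Methods

## Data model

A digitized leaf is an ordered grid: *n* full rows of five points
(`edge_left, mid_left, vein, mid_right, edge_right`), base to tip, one tip
point, and two stem reference points whose difference (lower → upper) is the
growth direction. Coordinates are centimetres in the digitizer's world frame,
with +Z vertical. The grid must have n ≥ 4 rows, distinct stem points and
distinct consecutive full-row vein points. The tip may coincide with the last
row's vein point (a blade digitized to its very tip): the final length
segment is then zero and the tip-fan facets have zero area, both handled
gracefully. On disk, leaves live in long-format delimited text
(`leaf_id, row_index, column_index, role, x, y, z`); the reader rejects
non-monotone row indices instead of sorting, so acquisition mistakes surface
rather than disappear, and parses floats in round-trip mode so write∘read is
the identity bit for bit.

## Local geometry

Rows i, i+1, i+2 form local patch i (n − 2 patches; the first and last rows
only ever serve as patch members). Each patch's plane is the classical
total-least-squares fit: the normal is the singular vector of least singular
value of the centered 15-point coordinate matrix, and the origin is the
orthogonal projection of the patch center (the middle row's vein point) onto
the plane. Degeneracy is declared when the second-smallest scatter
eigenvalue falls below 1e−12 of the largest (collinear points).

Orientation: the basal normal is flipped to a non-negative dot product with
the growth direction; an exact zero is broken by the sign of the mean
edge-point offset along the candidate normal, and a still-exact zero (a
perfectly symmetric, perfectly vertical blade — constructible synthetically,
vanishing probability with real noise) raises an orientation-ambiguity
error. Signs then propagate base to tip: each normal is flipped if it turns
more than 90° from its oriented predecessor. The procedure is idempotent and
equivariant under rigid motions.

Fallback: strongly rolled or twisted blades defeat the 15-point fit, so a
per-leaf gate on the first-pass traits — BST > r₁ or |OBIA_avg − 180| > r₂ or
OBIA_sd > r₃, defaults r₁ = 1.5, r₂ = 50.0, r₃ = 65.0 (configurable
`--r1/--r2/--r3`) — triggers a refit of *every* patch from its six bilateral
edge points, keeping the patch center as the origin anchor, followed by
re-orientation and full recomputation of the local traits. The gate is
whole-leaf because its conditions are whole-leaf statistics.

## Trait conventions

* Cross-section plane: T = (next row's vein point) − (patch center), T′ = the
  component of T in the patch plane, normalized; the cross-section plane
  passes through the patch center with normal T′. The same plane serves the
  blade-included angle and the twist angle — the only reading under which a
  flat blade yields exactly 180° and the normal lies inside the plane.
* θᵢ side test: the unsigned margin angle γ is kept when the mean of the two
  margin offsets along the normal, measured **from the vein point**, is ≥ 0
  (margins adaxial ⇒ inner rolling), else θᵢ = 360° − γ. The vein-centered
  reference matters under the fallback: the edge-fit plane passes nearly
  through the margins themselves, so a plane-referenced offset degenerates
  into fit noise and can mis-sign outer rolling, while the vein reference
  stays physically meaningful in both passes.
* φᵢ sign: positive when cross(Nᵢ, N′ᵢ₊₁) points along +T′ — counterclockwise
  under the right-hand rule looking from base toward tip. Mirroring the blade
  flips every φᵢ.
* BP sums |dᵢ|, although the summand is naturally signed: the trait is a
  magnitude (its population range is strictly positive and its sd is defined
  on absolute values). `--bp-signed` preserves the literal signed mean for
  comparison; signed d values are always used internally for MA.
* All standard deviations are sample (n − 1) deviations, conventional for
  trait tables. Consequences: OBIA_sd needs ≥ 2 patches (n ≥ 4) and OBST_sd
  needs ≥ 2 twist angles (n ≥ 5); full extraction on an n = 4 grid raises an
  insufficient-data error on OBST_sd by design rather than fabricating a 0.
* IA uses the chord from the row-0 vein point to the row-2 vein point
  (`--ia-rows`, default 2 — two segments damp single-point digitizing noise;
  a fitted basal tangent would be the alternative), measured against the
  horizontal plane. World +Z is vertical; the growth direction only
  identifies the adaxial side and never redefines the vertical.
* LL includes the tip segment (the tip is the (n+1)-th vein point). LA is
  always computed on the raw, unsubdivided mesh: the digitized facets *are*
  the measurement; subdivision exists for display only.

## Meshing

Quads between adjacent rows/columns are split along the fixed diagonal
(r, c) → (r+1, c+1) — for planar quads the diagonal choice does not change
area; for warped quads it does, which is why one fixed convention is used —
and the last row fans to the tip: 8(n − 1) + 4 faces on 5n + 1 vertices, a
topological disk (V − E + F = 1). Winding is flipped globally if the basal
band's mean facet normal opposes the growth direction, so face normals point
adaxially at the base.

Sqrt3 subdivision (Kobbelt): per step, a vertex at every face centroid,
1 → 3 face split, a flip of every original interior edge, and valence-based
relaxation of old interior vertices (α_k = (4 − 2 cos(2π/k))/9). Boundary
vertices are held fixed and boundary faces split without flips: the digitized
margin is signal and must not shrink. Faces triple and vertices grow by the
previous face count each step; the scheme is affine-invariant (planar meshes
stay planar) and deterministic. Export is ASCII OBJ (1-based indices) or
ASCII PLY (0-based) via trimesh.

## Synthetic leaves

The generator emulates the acquisition protocol on a parametric surface:

* **Vein**: unit-speed curve in the x = 0 plane; the tangent's elevation
  starts at the inclination and falls linearly at the droop rate
  (deg per unit arc position u). LL ground truth is therefore exactly the
  length parameter.
* **Cross-sections**: two straight half-blades meeting at the vein at the
  fold dihedral (180° flat; < 180° folded adaxially = inner rolling), so the
  blade-included angle ground truth is exactly the dihedral when the margin
  wave is off. With a wave, margins leave the fold planes and the labels are
  computed from the exact displaced geometry instead.
* **Twist**: the frame rotates about the local tangent by a cumulative
  profile. The default profile applies the labelled total twist between the
  second and third-from-last rows with flat tails: the discrete estimator
  only observes normals at patch centers (rows 1 … n − 2), and confining the
  twist to that span makes the label simultaneously the physically correct
  base-to-tip twist and recoverable from the samples.
* **Width**: parabolic half-width profile, maximal at the base, zero at the
  tip (configurable callable).
* **Margin wave**: sinusoid in u displacing only the two margin columns along
  the local adaxial normal — mid columns stay on the fold planes, isolating
  planarity/margin effects from the included angle.
* **Noise**: iid Gaussian on all leaf points, applied last, controlled solely
  by the seed.

Rows sit at u = r/n, the tip at u = 1. Defaults follow the reported
population means for field-grown ear leaves at grain filling: length 69.2 cm,
inclination 49.5°, fold 174°, total twist 35.3°, half-width 5.4 cm
(≈ 500 cm² area); unreported quantities were fixed once at field-realistic
values — droop 30°/u, margin wave 1.0 cm × 2.5 cycles, noise 0.05 cm
(≈ stylus precision). LA ground truth is a dense facet quadrature (1200
strips) of the continuous surface up to the last row plus the exact tip fan.

What the generator does *not* emulate: operator-dependent row spacing, sharp
localized creases, serrated or torn margins, self-occlusion/self-intersection
of extreme folds (not detected), or width-correlated allometry. Passing
recovery tests therefore demonstrates estimator correctness on smooth,
well-sampled blades, not robustness to every field artefact.

## Numerical choices

Angles are computed with atan2 forms (never bare arccos) and reported in
degrees; internal work is in radians. Unit tolerances: plane normals unit to
1e−9; projection/degeneracy epsilon 1e−9 relative; scatter degeneracy 1e−12
eigenvalue ratio. Trait tables print 7 significant digits, the least fixed
precision that re-reads within 1e−6 relative. Zero-area facets are summed as
zero with a logged warning. Problem sizes in the test and acceptance runs
(25–50 rows, 60–100-leaf populations) were chosen as the smallest at which
discretization error is comfortably below the stated recovery tolerances.

## Known limitations

* Margin amplitude is resolution-linked: it differences consecutive rows, so
  its value depends on row spacing (implemented as defined; comparisons are
  only meaningful at similar sampling density).
* The fallback gate's r-thresholds are adopted as given; they were calibrated
  on a particular field population and may need retuning for other canopies.
* A perfectly symmetric, near-vertical sharp V-fold has a genuinely ambiguous
  adaxial side and is rejected rather than guessed.
* Variance components for H² must come from an external mixed-model fit; the
  package only evaluates the formula.
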