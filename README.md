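# leaf3d

Quantitative 3D shape traits for structured, digitized maize leaves.

Maize (corn) ear leaves are anything but flat: they roll inward or outward,
twist along the midrib, buckle away from planarity and carry wavy margins.
These "computational phenotypes" cannot be read off with a ruler or a leaf
area meter, but they can be computed from a structured 3D digitization of the
blade: *n* rows of five points each (`edge_left, mid_left, vein, mid_right,
edge_right`), base to tip, plus one tip point (`5n + 1` points in all) and two
stem reference points that encode the plant's growth direction. `leaf3d`
turns such grids into thirteen morphological traits, builds triangle meshes
for visualization, and generates parametric synthetic leaves whose true trait
values are known — so every estimator is testable without field data.

## The traits

Global, from the raw grid:

* **LL** (cm) — leaf length: summed vein polyline, tip included.
* **LA** (cm²) — 3D leaf area: facet-area sum of the quad-split triangle mesh.
* **IA** (°) — inclination: elevation of the basal vein chord above the
  horizontal plane (world +Z vertical).

Local, from the *n − 2* overlapping three-row patches, each carrying a
total-least-squares plane with unit normal **N**ᵢ oriented consistently
(adaxial side, growth-direction anchored, base-to-tip sign propagation):

* **Blade-included angle.** In the cross-section plane through the vein point
  Pᵢ (normal = in-plane vein tangent **T**ᵢ′), the angle
  θᵢ = ∠P′ᵢ₋₂PᵢP′ᵢ₊₂ subtended by the projected margin points, mapped to
  (0°, 360°): inner rolling < 180° < outer rolling. Reported as `OBIA_avg`
  (oriented mean), `BIA_avg` (mean of θᵢ′ = min(θᵢ, 360° − θᵢ)) and `OBIA_sd`.
* **Blade self-twisting.** φᵢ is the signed in-plane angle from **N**ᵢ to the
  projection of **N**ᵢ₊₁ (counterclockwise about **T**ᵢ′ positive);
  `OBST = Σφᵢ / 180` (so OBST = 1.2 means 216° of accumulated twist),
  `BST = |OBST|`, plus `OBST_sd` (°).
* **Blade planarity.** Signed margin-to-plane distances dᵢ give
  `BP = mean |dᵢ|` and `BP_sd` (cm) over the 2(n − 2) margin points.
* **Margin amplitude.** Same-side consecutive differences |dᵢ₊₁ − dᵢ| give
  `MA_avg` and `MA_sd` (cm) — margin waviness.

Leaves whose first-pass traits betray an unreliable 15-point plane fit
(BST > r₁ = 1.5, |OBIA_avg − 180| > r₂ = 50 or OBIA_sd > r₃ = 65) are refit
per patch from the six bilateral edge points; the trait table flags these
with `fallback_used`.

For population work there is a Table-style trait summary and the generalized
(broad-sense) heritability H² = V_g / (V_g + V_gl/L + V_e/(L·R)) for
externally estimated variance components.

## Worked example

Simulate three leaves, extract their traits, summarize:

```sh
$ leaf3d simulate leaves.csv --n-leaves 3 --seed 7 --truth truth.csv
$ leaf3d extract leaves.csv traits.csv
WARNING leaf3d.traits_local: leaf leaf_0000: first-pass traits exceed the
thresholds (BST=0.226, OBIA_avg=235.6, OBIA_sd=72.5); refitting normals from
bilateral edge points
...
INFO leaf3d: extracted 3 leaves (2 via edge-point fallback) -> traits.csv
$ head -2 traits.csv
leaf_id,LL,LA,IA,BIA_avg,OBIA_avg,OBIA_sd,BST,OBST,OBST_sd,BP,BP_sd,MA_avg,MA_sd,fallback_used
leaf_0000,94.89949,872.6932,21.13858,93.84322,258.7181,42.8664,1.129343,-1.129343,1.601494,0.190147,0.1110308,0.1557794,0.1024079,True
```

Reading `leaf_0000`: a 94.9 cm, 873 cm² blade inserted at 21° above the
horizontal; `OBIA_avg = 258.7°` (> 180°) says the blade rolls outward,
away from the adaxial side; `OBST = −1.13` is a leftward twist of
1.13 × 180° ≈ 203° accumulated base to tip; BP ≈ 0.19 cm and
MA_avg ≈ 0.16 cm describe a fairly smooth surface and margin. Its rolling
pushed the first-pass gate (|235.6 − 180| > 50), so its normals came from the
edge-point fallback.

```sh
$ leaf3d summarize traits.csv
Trait            Mean                  Range
LL             84.843 [59.198, 100.431]
LA            618.140 [410.274, 872.693]
IA             18.707 [13.967, 21.139]
...
```

Meshes for inspection in any viewer (`--subdivide` applies Sqrt3 refinement,
tripling faces per step while keeping the digitized margin fixed):

```sh
$ leaf3d mesh leaves.csv meshes/ --subdivide 1 --format ply
```

The same functionality is available as a library:

```python
from leaf3d import SyntheticLeafParams, generate_leaf, extract_all_traits

grid, truth = generate_leaf(SyntheticLeafParams(twist_deg=216.0, noise_sd=0.0))
record = extract_all_traits(grid)   # record.OBST ~ truth.OBST = 1.2
```

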