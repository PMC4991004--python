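# Methods

`topolight` automates illumination design for direct volume rendering: the
contour tree of the volume supplies a structural index, and per-structure
Blinn-Phong parameters are generated from topological attributes instead of
being set by hand.  This note records the models implemented, the numerical
choices made where the design was genuinely open, and what the synthetic
test volumes do and do not demonstrate.

## Contour tree, branch decomposition, segmentation

The scalar field is treated as a function on the voxel graph, with a total
order `(value, linear index)` breaking ties ("simulation of simplicity"), so
every sweep event is distinct and constant regions cause no ambiguity.  The
join tree (superlevel-set components) and split tree (sublevel-set
components) are built by a sorted union-find sweep; they are combined into
the contour tree by iterative leaf transfer, and reduced to critical nodes
(extrema and saddles) with every regular voxel mapped to its arc.

**Connectivity.** On a cubical grid, the superlevel and sublevel sides must
use *dual* neighborhoods — 6/26, the 3D analogue of the 4/8 foreground/
background duality of 2D image topology.  With symmetric 6/6 (or 26/26)
connectivity the two merge trees can be genuinely incompatible (the
checkerboard paradox lifted to 3D: we found 5x2x3 grids with distinct values
whose join and split trees admit no common tree), and the combination step
then provably stalls.  `build_contour_tree(connectivity=6)` therefore uses 6
for the join side and 26 for the split side; `connectivity=26` swaps the
pair.  `build_merge_tree` still accepts any direction/connectivity
combination for callers who want the raw merge trees.

**Branch decomposition.** Branches are monotone extremum-saddle paths,
obtained by greedily pruning the leaf arc with the smallest importance
measure (persistence, volume, hypervolume, or importance-triangle area), so
surviving paths are the most important ones.  Two guards keep the result
canonical: a leaf arc is only prunable if its saddle retains another arc on
the pruned side (otherwise the remaining path through the saddle would lose
monotonicity), and the global extremum pair is reserved for the root branch.
The root therefore spans the global maximum-minimum pair whenever a
monotone path between them exists — always true for the fixture families
shipped here.  On adversarial fields whose contour tree is "W-shaped" no
such path exists, and the decomposition then releases one global extremum
into a child branch rather than failing.

**Segmentation.** Every voxel belongs to exactly one branch: regular voxels
to the branch owning their arc, saddle voxels to the branch whose path
traverses them (the parent side), so a child region is exactly the part of
its superlevel/sublevel component strictly beyond the attaching saddle.
The per-voxel labels are recorded during decomposition, making
`segment_field` a lookup; the labels always partition the volume.

**Simplification** iteratively removes childless leaf branches whose
measure falls below a threshold (or until a target branch count), smallest
first, re-examining parents as they become leaves; the root is never
removed and pruned branches donate their voxels to their parent.  Branch
count is non-increasing in the threshold, and an infinite threshold leaves
exactly the root.

## Branch attributes

Per branch: persistence (absolute scalar difference of its critical pair),
volume (voxel count of its region), hypervolume (Riemann sum of the field
over the region times the voxel volume, so grid spacing is honoured), depth
(root = 0), sibling and child counts, and attaching saddle value (for the
root: its lower endpoint).

The *importance triangle* combines the three importance measures: laying
normalized persistence, volume and hypervolume along three coplanar axes
120 degrees apart gives area `(sqrt(3)/4)(pv + v*hv + hv*p)`, symmetric and
monotone in each measure, zero iff two of the three vanish.  Normalization
is per sibling group (each measure divided by the group maximum; a
group-wide zero maps to zero) because the quantity is consumed when
distributing light among siblings.

*Topological saliency* is depth-weighted relative importance:
`S_i = t_i / sum_j exp(-d(i,j)^2 / r^2) t_j` with `t` persistence or
volume, `d` the topological-depth difference and `r` the maximum depth of
the tree.  For a flat tree (maximum depth 0) `r` is set to 1; all distances
are then 0 and saliency reduces to `t_i / sum t_j`.  S is scale-invariant
in `t` and lies in (0, 1].

## Lighting transfer functions

All mechanisms share ambient `k_a = 0.1`, specular `k_s = 0.2` and
shininess 32 across branches (only the diffuse term is structure-dependent;
these shared values are conventional mid-range choices).  The user weight
`w` (default 0.71) scales the diffuse term.

* **Saliency**: `k_d = w * S_i` — more important structures reflect more.
* **Distance**: `k_d = w * sigmoid(depth)` — strictly increasing in depth,
  range [w/2, w), so inner structures are brighter.
* **Attenuation**: a Stokes'-law analogue,
  `alpha = 2 eta xi^2 / (3 rho V^3)`, with water constants
  `eta = 0.001002 Pa.s` and `rho = 998.2071 kg/m^3` (20 C), frequency `xi`
  the branch's sibling count, and speed `V` user-controlled; Beer-Lambert
  falloff `f_att = exp(-alpha z)` with travelled distance `z` the branch's
  persistence then dims the diffuse and specular terms.  With SI constants
  and V in the hundreds the raw product `alpha * z` is vanishingly small,
  so persistence is normalized to [0, 1] and a documented scale factor is
  applied, calibrated once so that `V = 50, xi = 1, z = 1` yields
  `f_att = 0.5`; every monotonicity of the raw formulas (decreasing in V,
  increasing in xi and z) is preserved exactly.  Note the structure of the
  model: a branch with no siblings (`xi = 0`) is never attenuated, which is
  why dominant structures — the root branch in particular — survive a
  speed sweep undimmed while sibling structures fade.
* **Importance** (comparison mode): `k_a = w *` normalized persistence or
  volume, diffuse shared.  **Constant** and **conventional** (no specular)
  modes are included as baselines.

## Perceptual contrast model

Luminance (cd/m^2) is assigned per branch in two phases and then mapped to
diffuse coefficients by `k_d = w * L / max L` (diffuse reflection being the
most instinctive carrier of an object's lightness; ranking by `k_d` equals
ranking by luminance).

The JND threshold-versus-intensity curve covers the whole human vision
range as a piecewise function of `log10 L`: a scotopic floor of -2.86 below
-3.94, a rod transition `(0.405 x + 1.6)^2.18 - 2.86` to -1.44, a mesopic
linear regime `x - 0.395` to -0.0184, a cone transition
`(0.294 x + 0.65)^2.7 - 0.72` to 1.9, and Weber behavior `x - 1.255` above.
Log is base 10.  The published fit has a genuine downward discontinuity at
the cone-to-Weber boundary (0.948 vs 0.645 at x = 1.9); it is implemented
verbatim and the discontinuity is flagged by a test, not smoothed away.

**Initialization**: the root receives the user luminance L0; every child
receives its parent's luminance plus exactly one JND at the parent's level,
recursively.  **Optimization** walks the tree breadth-first.  A parent at
luminance L with contrast ratio gamma gives its children the base
`L' = L / gamma`; siblings split it by `L_ij = L' * f_b * f_d` where `f_b`
is the child's importance-triangle area normalized by its maximum possible
value `3 sqrt(3)/4` (so `f_b` is in [0, 1]) and
`f_d = (s_ij - s_min)/(s_max - s_min)` ranks siblings by saddle value
(singleton groups take `f_d = 1`; the 0/0 case has no ranking to express).
A candidate whose gap to the parent falls short of the JND is corrected by
adding the shortfall onto the initialization luminance; the correction is
applied at most twice (it is not guaranteed to converge in one step), after
which a floor `max(L, L_init, L_parent + JND(L_parent))` enforces both the
perceptibility bound and that no branch ends below its initialization
value.  The contrast ratio flows down the tree losing
`dh = (1/K) Q p / n_c` per branch — a hydraulic head-loss analogue with
conductivity `K = 300` (water through sand), flow speed `Q = 1` by default,
`p` the branch persistence normalized over the tree (making dh scale-free)
and `n_c` its child count — so deeper levels have smaller gamma and hence
relatively brighter children.  gamma is floored at 1e-3 to keep the base
luminance finite; with that residue rule gamma is monotone non-increasing
along depth, which supersedes any lower bound at the root ratio.  The model
is fully deterministic.

## Renderer

A CPU ray-caster, orthographic by default (simplest to reason about in
golden tests), marching front to back at half-voxel steps.  Scalars and
precomputed central-difference normals are interpolated trilinearly; branch
labels are looked up nearest-neighbor (labels are categorical).  Shading is
attenuated Blinn-Phong,
`C = (k_a + k_d f_att (N.L)) C_tf + k_s f_att (N.H)^n`, with white
specular, per-sample coefficients from the sample's branch, and zero-normal
samples shaded ambient-only.  Inside the ray loop the dot products use
absolute values (two-sided lighting): the gradient's sign depends on
whether a structure is a maximum or a minimum of the field, and one-sided
clamping would extinguish the diffuse term on the camera-facing side of
value-maxima structures.  Opacity is corrected for step size,
`a' = 1 - (1 - a)^(step/reference)`, rays terminate at accumulated opacity
0.99, and identical configurations produce bit-identical images.  The
per-branch constant color/opacity transfer function is deliberately simple
plumbing — the full topology-controlled transfer-function generation
problem is out of scope — so renderings are structurally, not
photometrically, comparable to production volume renderers.

## Synthetic volumes

* `ramp_volume`: f = x; one arc, two leaves; root persistence nx - 1.
* `multi_blob_volume`: sum of distinct-height isotropic Gaussians on a
  tilted background (tilt 1e-4 per voxel removes plateaus and pins the
  background minimum).  Well-separated blobs give one maximum leaf each;
  the child saddle sits on the inter-blob ridge.
* `nested_blob_chain` (alias `nested_shell_volume`): an axial profile with
  *designed* peak/valley values (peaks decaying toward 6 from 10, valleys
  rising toward 5 from 2.5) interpolated by monotone cosine segments and
  extruded with a radial Gaussian envelope.  All critical points lie on the
  axis with exactly the designed values, each merge saddle lies inside the
  previous branch's span, and the decomposition is a depth-0..levels-1
  chain with nested regions.  A geometrically concentric chain of shell
  ridges would *not* work: its merge saddles all lie on the root path,
  giving a depth-1 caterpillar — nesting in value, not just in space, is
  what produces branch depth.
* `add_noise`: seeded i.i.d. Gaussian noise.  Spurious topological features
  under i.i.d. noise have persistence up to about `sigma sqrt(2 ln n)`
  (extreme-value scaling, ~3.9 sigma at 12^3 voxels), so simplification
  thresholds meant to remove noise should sit at 4 sigma or above, not at
  the naive 3 sigma.

These fixtures have provable trees but are far simpler than real
volumes: no anisotropic spacing beyond what tests set explicitly, no
acquisition artifacts, no fine-scale texture, and topology that is low-depth
by construction.  Passing tests demonstrate correctness of the machinery
and the stated monotonicities/invariants, not visual quality on clinical or
microscopy data.

## Problem sizes

The shipped tests use grids up to 32 x 20 x 16 and images up to 48^2, which
keeps the full suite under a minute while leaving every code path
exercised; the random-grid oracle comparison uses 200 grids of up to 6^3
vertices, where the brute-force component-counting oracle is exact and
cheap.  The implementation is pure Python/NumPy with a per-vertex sweep, so
volumes beyond ~10^6 voxels are outside its comfortable range; the design
goal is correctness and inspectability, not throughput.

## Known limitations

* Degenerate "monkey" vertices (e.g. a vertex that is simultaneously a
  maximum and a split saddle) are handled structurally, but such vertices
  are classified by tree degree, not by a Morse-theoretic unfolding.
* The attenuation scale factor is a calibration, not physics: the raw
  Stokes/Beer-Lambert constants do not produce usable falloff at volume
  scale, and any implementation must choose an implicit unit mapping.
* The perceptual model guarantees its JND bound by a final floor; the
  two-pass shortfall correction alone does not provably reach it.
* Perspective projection is implemented but the test suite exercises the
  orthographic camera.
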