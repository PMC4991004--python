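# topolight

Topology-aware illumination design for direct volume rendering.

Setting up meaningful lighting for a volume rendering is tedious: every
structure usually receives the same ambient/diffuse/specular coefficients,
so illumination carries no information about which structures matter, how
they nest, or how they differ.  `topolight` automates the assignment.  It
builds the **contour tree** of a 3D scalar volume (CT/MR/microscopy-style
grids), decomposes it into branches — each branch indexing one spatial
structure — and generates per-branch Blinn-Phong parameters from the
branches' topological attributes.  A small CPU ray-caster renders the
result.  It is aimed at visualization researchers and tool builders who
want structure-dependent lighting without hand tuning.

## The model

Per-sample shading is attenuated Blinn-Phong,

```
C = (k_a + k_d · f_att · (N·L)) · C_tf + k_s · f_att · (N·H)^n
```

with `N` the normalized gradient, `L` the light direction, `H` the halfway
vector and `C_tf` the transfer-function color.  `k_a`, `k_s`, `n` are
shared; the structure-dependent parts come from the contour tree's branch
decomposition, per branch *i*:

* **attenuation** — a Stokes-law analogue `α = 2ηξ²/(3ρV³)` (water
  constants η = 0.001002 Pa·s, ρ = 998.2071 kg/m³; ξ = number of sibling
  branches; V = user-controlled speed) drives Beer–Lambert falloff
  `f_att = e^(−αz)` with `z` the branch persistence: lowering V dims
  sibling-rich, low-importance structures while structures without siblings
  (the dominant ones) keep their light;
* **saliency** — `k_d = w·S_i` with `S_i = t_i / Σ_j e^(−d(i,j)²/r²) t_j`
  the depth-weighted relative importance (t = persistence or volume);
* **distance** — `k_d = w/(1 + e^(−depth))`: deeper (inner) structures are
  lit more;
* **perceptual** — a two-phase Just-Noticeable-Difference model: each
  branch is first given its parent's luminance plus one JND (the piecewise
  threshold-vs-intensity curve of human vision), then luminance differences
  are amplified level by level through a contrast ratio γ that flows down
  the tree losing head `Δh = (1/K)·Q·p/n_c` per branch (K = 300), siblings
  sharing each level's budget by importance-triangle area and saddle rank,
  with every parent→child gap kept at or above one JND.

## Worked example

A synthetic volume with three nested structures (a depth-0/1/2 branch
chain):

```python
import topolight as tl

field = tl.nested_blob_chain((25, 16, 16), levels=3)
ct = tl.build_contour_tree(field)
bd = tl.simplify_tree(tl.decompose_branches(ct), "persistence", threshold=0.5)
seg = tl.segment_field(field, bd)
attrs = tl.annotate_structure(bd, field, seg)
print(tl.attributes_to_frame(attrs).round(3).to_string(index=False))
```

```
 branch_id  persistence  volume  hypervolume  depth  n_siblings  n_children  saddle_value  saliency  triangle_area
         0        9.763    5700     4654.244      0           0           1         0.000     0.637          1.299
         3        5.563     516     1884.112      1           0           1         2.444     0.352          1.299
        11        3.377     184      903.628      2           0           0         3.665     0.299          1.299
```

Branch 0 is the outermost structure (the root: largest persistence and
volume, depth 0); branches 3 and 11 are successively nested inside it,
attaching at increasing saddle values (2.44, 3.67).  Distance-mode lighting
then brightens inner structures:

```python
table = tl.build_lighting_table(attrs, tl.LtfConfig(mode="distance", weight=0.71))
# branch 0: k_d = 0.355   branch 3: k_d = 0.519   branch 11: k_d = 0.625
```

and the perceptual model assigns luminances whose parent→child gaps all
exceed one JND (JND(10 cd/m²) ≈ 1.37 cd/m²), amplified beyond the bare
initialization by the γ = 0.8 contrast ratio:

```python
la = tl.optimize_luminance(bd, attrs, tl.ContrastFlowParams(L0=10.0, gamma0=0.8))
# branch 0: L = 10.000 cd/m²  (init 10.000)
# branch 3: L = 12.500 cd/m²  (init 11.367)
# branch 11: L = 15.655 cd/m²  (init 12.869)
```

The same pipeline runs from the shell, one subcommand per stage:

```
topolight synth --kind nested_shells --dims 25 16 16 --levels 3 --out vol.nrrd
topolight pipeline --input vol.nrrd --mode perceptual --simplify persistence:0.5 \
    --out-prefix out/run
```

which writes `out/run_tree.json`, `out/run_attrs.csv`,
`out/run_lighting.json`, `out/run_image.ppm`/`.png`, and the perception
diagnostics CSV.  Volumes are read and written as NRRD or raw-plus-header;
see `docs/methods.md` for the models, numerical choices and limitations.

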