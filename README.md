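# gradorder

Tools for a question in visual psychophysics: when you look at a single
picture of an object, what in the image tells you its **material**, and what
tells you its **shape**? A productive hypothesis is that the two live in
orthogonal components of the intensity gradient field: the **gradient
magnitude** carries material information (it is what histogram manipulations
and tone curves change), while the **intensity order** — equivalently the
isophote structure, or the **gradient direction** map — carries shape
information and is largely invariant to material changes.

`gradorder` implements the computational machinery needed to state and test
that hypothesis on synthetic stimuli:

* **Scene synthesis** — surfaces modulated in depth by Gaussian band-pass
  noise, bumpy spheres (normals perturbed by band-pass noise), and distant
  point lights parameterized by slant/tilt.
* **Shading** — Lambertian, Ward (diffuse + rough-specular), and asperity
  (velvet-like) reflectance under local point-light shading:

  - Lambertian: `L_l = (rho_d / pi) * l * (I.N)`
  - Ward: `rho(θi, θo) = rho_d/pi + rho_s * exp(-tan²δ/α²) / (4πα² sqrt(cosθi cosθo))`
    with `δ` the angle between the normal and the light/view half vector
  - Asperity: `L_a = (a/pi) * l * (I.N) / (a + (I.N)(J.N))`

  plus diffuse/specular splitting, inconsistent-highlight composition
  (rotate/displace the specular pattern), and global intensity reversal.
  Under frontal light the asperity image is an analytic remapping of the
  Lambertian image, `L_a = a l_a L_l / (a rho_d l_l + π² L_l² / (rho_d l_l))`,
  which rises to a peak at `L_l = sqrt(a) rho_d l_l / π` and then falls —
  i.e. it *reverses* the intensity order on the top fraction `1 - sqrt(a)`
  of the range.
* **Tone operators** — rank-based histogram matching (with a
  `Beta(p, 10-p)` reference for skewness control), the compressive map
  `f(x) = 1 - [(1-x)^r + (1-c)^r]^(1/r)` that saturates at the cut-off `c`,
  and the linear+sinusoid remap
  `f(x) = s1 (x - m) + s2 sin(ω (x - m) + φ) + m`, which is order-preserving
  iff `s1 ≥ s2 ω`; diagnostics include monotonicity classification, sample
  skewness, and an order-preservation index (Goodman–Kruskal gamma over
  pixel pairs: 1 = order intact, −1 = reversed).
* **Gradient analysis** — 5×5 separable derivative filters (Farid–Simoncelli
  pair), magnitude/direction decomposition, small-gradient masking
  (threshold 0.0002), and pairwise material correlations on a synthetic BRDF
  family: circular correlation for direction maps, Pearson for magnitude
  maps, pixels pooled across geometries.
* **Gauge-probe statistics** — slant/tilt judgments as unit normals, angular
  differences aggregated trials → gauges → observers with percentile
  bootstrap CIs, tilt (circular) / slant (Pearson) correlations, and a
  simulated observer for end-to-end testing.

## Worked example

```python
from gradorder.pipeline import (PipelineConfig, SceneSpec,
                                run_material_correlation_study)

cfg = PipelineConfig(scene=SceneSpec(size=128), light_slants=[0.0, 40.0], seed=0)
summary = run_material_correlation_study(cfg)["summary"]
print(summary)
```

prints (values rounded):

```
median_dir_corr                  0.984
median_mag_corr                  0.724
min_lambert_ward_dir_corr        0.959
max_cross_illumination_dir_corr  0.296
direction_dominates_magnitude    True
lambert_ward_dir_above_0.9       True
cross_illumination_degrades      True
pass                             True
```

Reading: across a family of 19 materials (Lambert, a 4×4 Ward gloss sweep,
two asperity materials) rendered on three band-pass surfaces under a frontal
point light, the *direction* maps of the intensity gradient correlate at
0.96–1.00 between any Lambert/Ward pair, while the *magnitude* maps are far
less stable (median 0.72) — material changes leave the shape-bearing
direction structure alone. Rendering the *same* material under lights 40°
apart collapses the direction correlation to ≤ 0.30: direction constancy is
a within-illumination property.

The same machinery separates real highlights from albedo blobs:

```python
from gradorder.pipeline import run_highlight_consistency_demo
report = run_highlight_consistency_demo(cfg)["report"]
```

```
 cutoff   highlights  order_index_vs_diffuse
   0.25    veridical                1.000
   0.25 inconsistent                0.870
   0.35    veridical                1.000
   0.35 inconsistent                0.870
   1.00    veridical                1.000
   1.00 inconsistent                0.870
```

A veridical specular highlight never reverses the diffuse shading's
intensity order (index 1.0 at every compressive cut-off), whereas a
displaced/rotated highlight — which observers see as white paint, not gloss
— disrupts it at every cut-off.

There is also a CLI:

```bash
gradorder render --geometry sphere --material ward --out scratch/sphere
gradorder study monotonicity-grid
gradorder study material-correlations --seed 0 --out scratch/study
gradorder probe-stats --a judged_a.csv --b judged_b.csv --n-boot 10000 --seed 7
```

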