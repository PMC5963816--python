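# Methods

This note records the models implemented by `gradorder`, the parameter
choices that matter, and the numerical decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate and image conventions

Pixels are 0-based, row-major; x increases with the column index, y
increases *upward* (against the row index). Consequently a gradient
direction of 0 rad points right and π/2 points up, and analytic ramps have
analytic directions. The camera is orthographic on +z with viewing
direction (0, 0, 1); a light of slant σ and tilt τ arrives from
(sin σ cos τ, sin σ sin τ, cos σ). Slant 0 is frontal light. Perspective
projection is not emulated: none of the analyzed properties depend on
projection.

`IntensityImage` stores values normalized to [0, 1] by the masked radiance
maximum, which is kept as `white_point` so raw radiances round-trip exactly.
Normalizing by the maximum is the simplest order-preserving display mapping;
any monotone alternative would leave every statistic in this package
unchanged except absolute magnitudes.

## Scene synthesis

Band-pass height fields filter white Gaussian noise with an annular Gaussian
amplitude spectrum centered on `center_freq` (default 8 cycles/image) with
radial s.d. `center_freq·rel_bandwidth/3` (default `rel_bandwidth` 0.5).
The /3 factor keeps comfortably more than 80% of spectral power inside
[f₀/(1+b), f₀(1+b)], which is the package's working definition of the pass
band and is asserted by FFT in the tests. The DC term is zeroed (zero mean)
and the field is rescaled to RMS `amplitude`; amplitude 0 short-circuits to
an exactly flat field. Default amplitude 4 (depth units at unit pixel
pitch) gives an RMS slope ≈ 0.8 at 256², i.e. clearly bumpy surfaces whose
normals stay front-facing — chosen once as a visually plausible stand-in
for noise parameters that are not otherwise pinned down.

Bumpy spheres start from exact hemisphere normals on the inscribed disc
(pixels at or beyond the disc radius are masked out, not clamped); the two
in-plane normal components are perturbed by independent band-pass noise
fields of RMS `bump_amplitude` and renormalized. Because the z component is
untouched before renormalization, perturbed normals remain front-facing.

Height-field normals are normalize(−∂z/∂x, −∂z/∂y, 1) with central
differences (`numpy.gradient`), exact for planes.

## Shading

All three reflectance models are evaluated locally per pixel: no cast
shadows, no interreflection, no environment light. Incidence and exitance
cosines clamp at 0, so attached shadows are black (there is no ambient
term). For the Ward model the specular energy denominator is the standard
`sqrt(cosθi·cosθo)`; a `denominator="printed"` switch evaluates the
unrooted `cosθi·cosθo` variant for comparison, since both forms circulate
in the literature. Pixels with non-positive incidence or exitance cosine
get zero in both terms, so no division by zero can occur.

The diffuse/specular/combined split shares one white point (the combined
maximum), so `diffuse.values + specular.values == combined.values` holds
identically. Inconsistent highlights rotate the specular radiance map
about the image center and shift it by (dx, dy) pixels, with out-of-frame
content dropping to zero; nearest-neighbor resampling is the default so a
180° rotation is an exact involution (bilinear is available). The default
transform (rotation 90°, shift 10% of width) is configurable.

Asperity parameters follow the frontal-light analysis: `l_a = π` for
a = 0.2 and `4π` for a = 0.02 (the darker, more strongly reversing velvet
needs a brighter light to use the display range). With `rho_d = 0.6`,
`l_l = π`, the Lambertian range is [0, 0.6] and the asperity remap peaks at
`sqrt(a)·0.6`.

## Tone operators

**Histogram matching** is rank-based: the pixel of rank k among the n
masked-in pixels receives the k-th order statistic of the reference sample
(resampled by quantiles at (k−0.5)/n when sizes differ). Tied input pixels
receive the *mean* of their group's reference values, so ties are preserved
exactly and the matched image has exactly the input's intensity order.
(Breaking ties by pixel index would map equal inputs to unequal outputs and
spuriously register order disruption on images with flat regions, e.g.
attached shadows.)

**Beta reference.** Quantiles of Beta(p, 10−p) at (i−0.5)/n via the
regularized incomplete beta inverse (`scipy.stats.beta.ppf`), affinely
rescaled to the target mean/SD using the sample moments (exact before
clipping to [0, 1]); clipping-induced moment drift is the user's signal to
reduce `target_sd`. The analytic skewness of Beta(8.5, 1.5) is 1.0836 in
magnitude — the "±1.1" skewness setting. The sign convention of p is
ambiguous in the source literature (p = 8.5 can label either the positive
or the negative tail depending on which exponent carries p), so the package
asserts magnitudes and exposes `flip` to mirror the distribution.

**Compressive map.** `f(x) = 1 − [(1−x)^r + (1−c)^r]^(1/r)` is a smooth
minimum of x and the cut-off c: nondecreasing, ≈ identity below c, and
saturating at c with smoothing r (default 30; an `auto` cut-off of
masked mean − 1 SD is provided). The formula also circulates without the
leading "1 −", which is a *decreasing* function; that literal variant is
kept behind `as_printed` for comparison but contradicts the intended
"output levels off beyond a certain input intensity" behavior. The map is
evaluated in log space (`logsumexp`), since the direct power form
underflows for large r.

**Sinusoid remap.** `f(x) = s1(x−m) + s2 sin(ω(x−m)+φ) + m`, clipped to
[0, 1], with ω = 2.857π and φ = π as used in the remapping experiments
(φ = π makes the mean intensity a fixed point). Monotonicity on a domain
covering at least one modulation cycle is decided analytically by the sign
of s1 − |s2|ω; shorter domains fall back to a dense derivative grid. On
the 3×5 experiment grid exactly five curves are non-monotone:
(0.5, 0.065), (0.5, 0.115), (0.5, 0.165), (1, 0.115), (1, 0.165).

**Order-preservation index.** Goodman–Kruskal gamma over masked pixel
pairs: (concordant − discordant)/(concordant + discordant), ignoring pairs
tied in either image; computed from Kendall's tau-b and the tie counts in
O(n log n). Gamma — rather than a midrank rank correlation — is the right
operationalization of "intensity order information" here because a
saturating tone map collapses the top of the intensity range into ties
(genuinely so in the r → ∞ limit min(x, c)) while reversing no pair; order
*disruption* means reversal, and gamma is exactly 1 for every nondecreasing
remap, −1 for a global reversal, and ≈ 0 for a random permutation.

**Skewness** is the biased moment estimator m₃/m₂^{3/2}, matching common
usage in the texture-statistics literature.

## Gradient analysis

Derivatives use the Farid–Simoncelli 5-tap matched prefilter/derivative
pair (coefficients frozen in `gradients.py` for bit-stability), applied
separably; direction = atan2(gy, gx) signed modulo 2π, with an unsigned
modulo-π orientation view available for comparison. The validity mask is
the image mask eroded by the 5×5 support, so no silhouette-crossing
support enters the statistics; with `exclude_border=True` (default) the
2-pixel frame is excluded as well, while `exclude_border=False` keeps
full-frame images fully valid (reflective boundary handling), which is what
makes three 256² frames pool to exactly 196,608 pixels. Gradients with
magnitude below the threshold (default 0.0002) can be excluded, mirroring
the treatment of near-flat regions after strong tone compression.

**Circular correlation.** Two estimators are provided.
`method="mean"` is the Jammalamadaka–SenGupta statistic
Σ sin(αᵢ−ᾱ) sin(βᵢ−β̄)/√(Σ sin²(αᵢ−ᾱ)·Σ sin²(βᵢ−β̄)) with circular means.
`method="pairwise"` is the Fisher–Lee statistic on all pairwise angle
differences, evaluated in closed form in O(n). Both are invariant to
constant rotations of either series. The material analysis uses the
pairwise form: gradient-direction maps of isotropic bumpy surfaces are
close to uniform on the circle (resultant length ~10⁻³ at 256²), so the
circular mean that anchors the JS statistic is determined by noise, and
pooling several geometries can send the JS value of two nearly identical
direction maps toward 0 even though every per-geometry value is ≈ 0.95.
The pairwise form needs no mean and is stable under pooling.

A consequence of rotation invariance worth recording: an intensity-order
*reversal* flips every gradient direction by exactly π, a constant
rotation, so any circular correlation scores a perfectly reversed map +1.
The reversal produced by asperity scattering is therefore quantified with
`direction_agreement` = mean cos(Δdirection), which is −1 under a
whole-map flip (measured ≈ −0.995 against Lambert over the reversed range
for a = 0.02).

**Pairwise material study.** The default family is Lambert plus a Ward
sweep ρs ∈ {0.05, 0.15, 0.25, 0.4} × α ∈ {0.05, 0.1, 0.25, 0.4} (all with
ρd = 0.5) plus asperity a ∈ {0.2, 0.02} — 19 materials, 171 unordered
pairs. Each pair is rendered on every geometry, gradient masks are
intersected per geometry, and valid pixels are concatenated across
geometries (pooling pixels, not averaging per-geometry correlations, which
is what the 196,608 = 3 × 256² count implies). The summary reports the
median direction and magnitude correlations among smooth (Lambert ∪ Ward)
pairs, the minimum Lambert–Ward direction correlation, and the maximum
same-material direction correlation across the 0°/40° illumination pair.

## Gauge-probe statistics

Gauge settings are (slant, tilt) ∈ [0, 90] × [0, 360) mapped to unit
normals; the angular difference between two settings is
2 arcsin(‖n₁−n₂‖/2) — algebraically arccos(n₁·n₂) but exactly 0 for
identical settings and stable near parallel normals. Differences are
reported in radians (the scale on which cross-illumination control values
like 0.25 ≈ 14.3° are dimensionally natural); the CLI can print degrees.

Aggregation is hierarchical — trials → gauges → observers — and the 95%
CI is a percentile bootstrap over observers (default 10,000 resamples,
seeded; BCa was not used because observer counts here are small and the
percentile form is the transparent default). Tilt/slant correlations use
per-(observer, gauge) trial means: circular means for tilt, arithmetic for
slant; then circular correlation of tilts and Pearson of slants.

The simulated observer perturbs the true normal by a tangent-plane
bivariate Gaussian with per-axis angular SD `noise_deg` and renormalizes;
its expected angular error is E[arctan ‖e‖], e ~ N(0, s²I₂). The
bootstrap-coverage experiment in the acceptance suite uses 15 observers ×
9 probes × 3 trials at 8° noise with probes restricted to slants < 50°, so
the slant ≤ 90° gauge clamp never binds and that analytic truth applies;
200 seeded replications are checked against the 95% CI. Percentile
bootstraps undercover slightly at small observer counts, which is why the
experiment uses 15 observers rather than fewer.

## Problem sizes and determinism

The correlation analysis runs at 256² with three geometries (the analysis
resolution throughout); unit tests use 64–128² versions of the same
generators. All generators and studies are pure functions of their
parameters and a seed; pipeline stages draw per-stage seeds from one
`SeedSequence`, so reruns are byte-identical (asserted on the CSV outputs).

## What the synthetic data does and does not show

The generators emulate the *structure* of the original stimuli — band-pass
bumpy geometry, point lights at the analyzed slants, parametric gloss and
velvet — but not measured BRDFs, environment illumination, global
illumination (shadows/interreflections), or human observers. Passing tests
therefore establish the image-computational claims (what material changes,
tone operators, and illumination changes do to gradient magnitude,
direction, and intensity order) and the correctness of the statistics; they
do not re-establish the psychophysical findings, and the simulated observer
is a noise model, not a model of human shape perception. Mirror-like
materials, textured objects, and line drawings are outside the model class
on principle: histogram-style manipulations cannot produce them.

## Known limitations

* Local shading only; environment maps and measured-BRDF ingestion are out
  of scope (the BRDF family is parametric by design).
* The Ward denominator convention and the Beta skewness sign are genuinely
  ambiguous in the source literature; both are exposed as switches rather
  than resolved.
* The JS circular correlation is reported as specified but should not be
  trusted on near-uniform angular data; use the pairwise estimator there
  (the analysis default).
* At 256² with 19 materials the full three-light study takes tens of
  seconds on one core; the cost is dominated by the O(pairs × pixels)
  correlation stage.
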