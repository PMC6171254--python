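# Methods

## Hemodynamic model

The package post-processes a wall shear stress (WSS) vector field sampled on
the faces of a triangulated aneurysm + parent-vessel surface over one cardiac
cycle. WSS is the tangential viscous traction μ · (∂u/∂n) at the wall
(`wss_from_gradient` exposes exactly that product for scalar inputs); the
field itself is an input — this package does not solve for flow.

**Cycle integrals.** The oscillatory shear index per face,
OSI = ½ (1 − |∫ wss dt| / ∫ |wss| dt), uses trapezoidal quadrature on the
provided time grid. Two sampling conventions are supported through the
optional `period` of `WallFieldSeries`: if `period` is unset, the first and
last samples are taken to sit one full period apart (the endpoints are the
same cardiac phase) and the plain trapezoid applies; if `period` exceeds the
sampled span, the quadrature appends the wrap interval pairing the final
sample with the first. For a series of two equal-magnitude, opposite-direction
half-cycles both conventions give OSI = 0.5 to the last bit, because the
mixed transition intervals cancel exactly. Faces whose cycle-integrated |WSS|
falls below 10⁻¹² are assigned OSI = 0: with no flow there is nothing to
oscillate, and this avoids 0/0. OSI is clipped to [0, 0.5] to absorb
quadrature round-off (the vector integral can never analytically exceed the
magnitude integral).

**Diastolic instant.** The normalization below samples WSS "at diastole". If
the series does not carry an explicit `diastolic_index`, the default policy
takes the time sample minimizing the sac-area-weighted mean |WSS| — the
low-flow phase — and is overridable in `RunConfig`.

**WSS normalization.** With WSS_min/WSS_max the extremes of the diastolic
WSS magnitude over the sac faces (element-wise, sac = faces above the neck
plane), the normalized WSS is the [0, 1] root of the quartic ellipse relation
(x − 1)⁴ + u⁴ = 1, u = (WSS − WSS_max)/(WSS_max − WSS_min), i.e.
x = 1 − (1 − u⁴)^¼. The quartic has two real roots 1 ± (1 − u⁴)^¼; the lower
branch is selected so that x(WSS_max) = 0 and x(WSS_min) = 1 and the range is
[0, 1]. The quartic deliberately concentrates resolution at the low-WSS end:
x rises steeply only as WSS approaches the sac minimum. Faces outside the sac
range (normalization is evaluated on the whole mesh) are clamped to u ∈
[−1, 0]. The range WSS_max − WSS_min must exceed 10⁻¹² Pa; a flatter range is
a degenerate input and raises.

**CHP.** OSI_norm = 2 · OSI maps [0, 0.5] to [0, 1]; the combined
hemodynamic parameter is the convex blend CHP = w₁ · WSS_norm + w₂ · OSI_norm,
exactly linear in w₁ for fixed fields. w₁ = 1 (pure normalized WSS) is the
default operating point.

**Peak patch.** The predicted thin-walled area is the sac patch (faces whose
centroids lie within `mesh_patch_radius`, default 0.5 mm, of a seed face
centroid — Euclidean distance as a geodesic proxy, adequate for smooth sacs
at this radius) with the largest area-weighted mean CHP. Near-ties within
round-off (10⁻¹² relative) break toward the lowest face index so results are
deterministic, e.g. on constant fields.

## Colorimetric model

Images are 8-bit sRGB; decoding uses the standard IEC transfer curve and the
D65 / 2° observer CIELAB transform (via scikit-image). The color difference
is full CIEDE2000 with parametric factors k_L = k_C = k_H = 1, validated in
the test suite against the published verification pairs to 10⁻⁴.

The reference color (L₂, a₂, b₂) is the unweighted pixel mean over a
clinician-style circular annotation on normal vessel. The modified metric
ΔE_m = ΔE₀₀ · a₂² / (L₂² + a₂²) scales the whole map by one constant in
[0, 1], so within an image ΔE_m preserves pixel rankings while weighting the
comparison toward images whose reference is itself strongly red. The printed
squared form is the default; a cosine-projection reading a₂ / √(L₂² + a₂²)
is available as `delta_e_variant="projection"` but is never chosen silently.
b₂ is carried but unused by the formula. A reference with L₂ = a₂ = 0 leaves
the factor undefined and raises.

The reddest region is the argmax of the disk-mean-filtered ΔE_m map (default
radius 5 px — areas, not single pixels), restricted to the annotated region
of interest; means are computed over ROI pixels only, ties break row-major.
Per-pixel ΔE with patch means afterwards (rather than ΔE of patch-mean
colors) is the implemented reading.

## Statistical protocol

Each case contributes one value per hemodynamic parameter at the
more-dangerous (max-ΔE_m) and less-dangerous sites. Normality of each group
is screened with Shapiro–Wilk at α = 0.05 (same threshold as significance);
if either group fails, the comparison routes to the Mann–Whitney U test,
otherwise to the t test. Tests are two-sided and independent-samples by
default — Welch's t, since the observed group spreads differ severalfold —
with a paired option (paired t / Wilcoxon) since the sites are in fact
paired per aneurysm. Mann–Whitney uses the exact null distribution when both
groups have n ≤ 8 with no ties, the tie-corrected normal approximation
otherwise; the exact path is verified against exhaustive rank enumeration.
A constant sample can never pass a normality screen and routes to the rank
test; degenerate comparisons (all values identical in both groups) raise.
The weight sweep recomputes per-case CHP on a w₁ grid (default 0.5 … 1.0,
step 0.1) and repeats the gated comparison per row; group means are affine
in w₁ by construction, which the tests check to 10⁻¹².

## Synthetic cases: what they emulate, and what not

`make_case` builds an icosphere "dome" (default radius 2.55 mm, half the
~5.1 mm mean clinical aneurysm size; sac = upper hemisphere), a tangential
WSS field aligned with a fixed flow direction and modulated by a strictly
positive two-harmonic raised-cosine waveform q(s) = 0.82 + 0.55 cos 2πs +
0.18 cos 4πs (systole/diastole contrast ≈ 3.6:1, T = 32 samples over a
0.9 s cycle), per-face log-normal texture (σ = 0.08), and a planted
thin-wall patch: a cosine-squared angular bump (half-width 0.5 rad) that
multiplies WSS down to a factor 0.2 at its centre (matching the observed
more/less-dangerous WSS ratio ≈ 0.34/1.76) and reverses the WSS direction
for 15% of the cycle centred on diastole (10% outside the patch, so
background OSI is small but nonzero and the OSI contrast is modest — the
observed pattern). Pressure is a constant ~15.75 kPa plus small noise, with
no planted site effect. Ground-truth masks are the bump's upper half
(weight > ½).

The matched image is an orthographically projected, gently Lambertian-shaded
dome rendered in Lab (lighting deliberately mild: in real operative fields
redness, not shading, carries the thin-wall signal, and ΔE_m's constant
factor cannot discount within-image lightness gradients), with a co-located
+a* shift (default +15, slight −3 L* darkening), Gaussian Lab noise
(σ = 1.5), and annotation circles placed on normal vessel (reference, a
quarter-turn away in azimuth), at the patch centre (more dangerous) and
diametrically opposite in azimuth (less dangerous); the ROI is the central
85% of the dome, keeping the extreme foreshortened rim out of the search.
`make_cohort` jitters geometry, base WSS, patch placement and effect sizes
multiplicatively per case (null effects are preserved under the jitter) and
samples every parameter at both ground-truth sites (0.4 mm patch means).

These cases exercise the full pipeline but are not hemodynamically or
photometrically realistic: no secondary/vortical flow structures, no
Womersley profile (only the pulsatile character matters here), no specular
glare, white-balance error or perspective, no atherosclerotic thick-walled
confounder — the known clinical failure mode where the reddish area and the
CHP peak genuinely disagree is noted, not simulated. Passing tests therefore
demonstrate internal consistency and recoverability of a planted signal at
clinically-scaled effect sizes, not clinical performance.

## Correspondence, problem sizes, numerics

The two predictions agree when the peak-CHP patch centre lies within
`correspondence_tol` (default 1.5 mm) of the surface point under the
max-ΔE_m pixel, using the known synthetic camera mapping (clinically this
alignment is manual; no registration is attempted). Cohort analyses use 21
cases, mirroring the clinical cohort size; the planted-signal recovery suite
uses 40 single cases at the default icosphere resolution (1280 faces,
200 × 200 px images) and the null-calibration suite uses 1000 replicates of
two n = 21 samples — sizes chosen so the whole suite runs in well under a
minute while keeping binomial noise far from the asserted margins. All
randomness flows from explicit seeds; repeated runs are bit-identical.
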