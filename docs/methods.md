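# Methods

## Data model and conventions

All stages operate on a shared rectilinear voxel grid (`GridGeometry`):
0-based indices ordered (x, y, z), z craniocaudal, physical spacing in mm.
Images (`SUVImage`) are body-weight SUV, constrained non-negative and
finite; target volumes (`BinaryMask`) are boolean grids on the same
geometry, and combining objects on mismatched grids is an error, never an
implicit resample. Volumes are voxel counts times the voxel volume
(sx·sy·sz/1000 cc) with no sub-voxel surface correction — the behaviour of
clinical planning systems, and the definition every oracle in the test
suite uses. The default simulation grid is isotropic 2 mm, matching typical
PET reconstruction slice thickness; spacing is configuration, not a guess
at any particular scanner matrix.

SUV conversion is the standard body-weight form,
SUV(v) = C(v)·w/A(t), with C in Bq/mL, body weight w in grams, and the
injected activity decayed to scan start by 2^(−t/T½) (T½ = 109.77 min for
F-18, uptake delay default 60 min).

## Threshold protocol

The segmentation threshold τ is individualized per exam as the healthy-liver
background SUVmax: spherical ROIs of 20–30 cc (default 25 cc) are placed
fully inside the supplied healthy-liver mask by seeded rejection sampling
(a candidate centre is accepted when the mask's Euclidean distance
transform shows the sphere fits, and it does not overlap previously placed
ROIs). Three ROI SUVmax values are measured; if their spread is below
0.1 SUV they are kept, if within 0.1–0.2 two further ROIs are added, and a
spread above 0.2 is a protocol failure. τ is the arithmetic mean of the
retained values — the aggregation is a design choice: the repetition rule
exists to stabilize a noisy estimate, and averaging is the estimator that
does that. Tumour membership is strict: SUV > τ.

In the automated pipeline a failed measurement set is discarded and
re-measured in freshly drawn ROIs (bounded retries), the analogue of an
operator repeating the measurement elsewhere in the liver. On gated exams
τ is measured on the phase matching the reference planning CT phase, which
is explicit configuration (`PipelineConfig.reference_phase`), since phase
assignment to the CT is outside this package's scope.

## Segmentation, lesion identity, BITV

Per-phase masks are connected components under 26-connectivity (blob-like
PET lesions should not split on corner contact); components below a minimum
volume (default 0.1 cc, far below any clinically relevant lesion) are
discarded as noise specks. Lesion identity across phases is greedy:
largest voxel overlap against each identity's most recent mask, falling
back to nearest centroid within a capture radius (default 15 mm);
unmatched lesions start new identities, so a lesion present in only one
phase — the mechanism by which gating reveals lesions that the blurred
time-average hides — is represented, not an error. The BITV is the
voxel-wise union of one lesion's masks over the phases where it appears;
"union" rather than arithmetic volume addition is what makes the BITV an
internal target volume.

The non-gated BTV is seeded: threshold, then the component containing the
seed point (or the nearest within the capture radius); no reachable
component yields an empty mask with a warning rather than an error.

## Margin expansion

A "radial r / craniocaudal c" margin is morphological dilation by the
ellipsoid (dx/r)² + (dy/r)² + (dz/c)² ≤ 1, computed from the Euclidean
distance transform of the mask complement with the voxel spacing divided
per-axis by the margin, thresholded at 1 (+1e-9 so exact-boundary offsets
are included deterministically). This is exactly a Minkowski sum with the
set of voxel-centre offsets inside the ellipsoid — the test suite pins it
against a literal offset-union — and handles anisotropic grids without
resampling. PTVg = BITV + 3 mm isotropic; PTV = CTV + (5, 10) mm.

Two numerical consequences of the voxel-centre semantics are worth knowing.
First, against the continuum dilation it under-covers the boundary by
roughly half a voxel, about −3% in volume for centimetre-scale spheres at
1 mm spacing; tests of analytic dilated volumes therefore use a 4%
tolerance while the Minkowski-sum comparison stays exact. Second,
expanding in two steps reaches only sums of in-kernel offsets, so
expand(expand(m, a), b) is a subset of expand(m, a+b), close on fine grids
(within 5% in volume for 3+4 vs 7 mm at 1 mm spacing).

## Workflows

Gated: τ from the reference phase → per-phase BTVs → cross-phase matching →
per-lesion BITV → PTVg. Conventional: τ from the time-averaged exam → BTV →
CTV → PTV. The CTV is the clinician's manually edited volume when supplied
(`ctv_override`, the faithful path); otherwise the BTV clipped to the liver
mask stands in for the manual exclusion of lung/bone/organ-at-risk uptake
so that unattended end-to-end runs are possible. The comparison report
(volumes at 1 decimal, ratios as integer percent, exact Wilcoxon results)
follows the shipped JSON schema.

## Statistics

The cohorts are small, so the paired Wilcoxon signed-rank test is exact:
zero differences are dropped before ranking (Wilcoxon's original
treatment — required for the 7-effective-pair threshold comparison),
absolute differences get mid-ranks for ties, W is the smaller of the
positive/negative rank sums, and the two-tailed p is twice the lower tail
of the exact null distribution, capped at 1, enumerated by dynamic
programming over doubled (hence integer) rank sums — feasible to n = 25,
beyond which the tie-corrected normal approximation is used and labelled as
such. Summaries report per-column mean, sample SD, min, max, and
ratio-of-means ×100 for PTV/PTVg and BITV/BTV (ratio of means, not mean of
per-lesion ratios, which is a different and larger number). Lesions are
treated as independent pairs even when a patient contributes several; no
within-patient correlation is modelled, a deliberate mirror of common
pilot-cohort practice and a known limitation.

The packaged threshold table's non-gated column has a computed median of
3.75 SUV; published summaries of the same numbers print 3.8 (rounding).
The package always reports the computed value.

## Synthetic phantom generator

`PhantomSpec` describes static compartments (axis-aligned ellipsoids and
z-cylinders: body, lungs, mediastinum, liver) painted by fractional voxel
occupancy (3× per-axis supersampling, so rasterized volumes converge to
analytic values), hot spheres inside the liver, craniocaudal sinusoidal
sphere motion z(t) = A·cos(2πt/T), an isotropic Gaussian PSF (FWHM default
6 mm — the system-level resolution of clinical whole-body PET, not the
reconstruction filter width), and optional noise. Each phase bin is the
average of 5 supersampled time points within the bin (residual intra-gate
blur, as in real gated PET; static acquisitions skip the time sampling, and
snapshot tests use one sample per bin). The non-gated image is the
phase-fraction-weighted voxel mean. Everything is a deterministic function
of (spec, seed); noise streams are phase-indexed (`seed`, phase).

Presets: `jaszczak_preset` (static cylinder, 16/8/4 cc spheres at SUV 2/4/8
in backgrounds 1.17/1.19/1.23), `torso_preset` (liver/lung/mediastinum
compartments, 16 cc @ SUV 7.9 or 8 cc @ SUV 5.6 in a 2.97 liver background,
lesion off-centre in the right lobe so a healthy-liver region deep enough
for background ROIs remains), and `occult_lesion_preset` (5 mm radius,
SUV 6.5, ±12 mm excursion — constructed so the time-averaged image has no
supra-threshold voxel while every gated phase does). `simulate_gated` also
returns ground-truth sphere masks at bin-centre positions, the liver mask,
and a healthy-liver mask that excludes a capsule around each lesion's full
excursion (radius + 1.5·FWHM).

Noise model: white Gaussian added to the post-blur image, s.d. =
σ₀·√SUV (a scaled-Poisson surrogate; σ₀ default 0.15, ~9% voxel CoV at
liver background), clipped at zero to preserve SUV non-negativity. What
the generator deliberately does **not** reproduce: reconstruction-correlated
noise textures, attenuation/scatter effects, irregular breathing, and the
physiological heterogeneity of real livers. That last omission matters for
one statistic: in real exams the healthy-liver SUVmax sits ~1.5× the mean
background *and* repeats within 0.2 SUV between ROIs; a homogeneous
background with stationary noise cannot produce both at once (the
mean-to-spread ratio of an ROI maximum is capped by √(2·ln n) statistics),
and the default honours the repeatability condition, putting the measured
τ/background ratio nearer 1.3. Passing tests on this phantom therefore
demonstrate the pipeline's correctness and the direction and mechanism of
its biases, not scanner-accurate magnitudes.

## The analytic blurred-sphere oracle

`analytic_blurred_sphere_volume(R, A, b, σ, τ)` evaluates the closed-form
radial profile of a uniform ball convolved with an isotropic Gaussian
(erf/exponential terms, with the r→0 limit handled analytically; verified
against direct numeric radial integration to machine precision), finds the
iso-SUV radius by Brent root-finding, and returns the enclosed volume. It
requires b < τ < peak; τ at or below background has no iso-surface and is
rejected. In the σ→0 limit it returns the true sphere volume for any τ
strictly between background and sphere value. This is the independent
reference for threshold segmentation of blurred spheres: thresholds near
background inflate the volume (the partial-volume overestimation seen on
physical phantom measurements), monotonically less so as τ rises.

## Problem sizes and numerical choices

Simulated evaluations use 64³–96³ grids at 2 mm; analytic-dilation checks
use 1 mm grids of a few cm extent. Root-finding tolerance 1e-10 mm;
dilation boundary tolerance 1e-9 on the unit distance; supersampling 3×
spatial, 5× temporal. Fixed seeds make every simulation, ROI draw and test
deterministic.
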