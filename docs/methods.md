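# Methods

## Coordinate conventions

Volumes are indexed `[z][y][x]` with x the A-line (fast) axis, y the B-scan
axis and z depth, increasing posteriorly. Physical coordinates are
voxel-center based (`x_um = (ix + 0.5)·dx`), which makes lateral resampling
symmetric under volume flips. The default geometry is a 3 × 3 mm, 2.6 mm
deep cube of 256³ voxels; all computations carry physical units (µm), so
other grids work unchanged. En-face polar coordinates place the origin at
the BMO center with θ measured counter-clockwise from +x; half-axes are
indexed i = 0…M−1 at θᵢ = i·Δθ, and pseudo-radial image k (k = 0…M/2−1)
contains half-axes k and k+M/2, so Δθ = 15° yields 12 displayed images but
M = 24 half-axes for modeling.

## Reslicing

Pseudo-radial images sample each z plane bilinearly along the cut; there is
no interpolation in z, since the cut is parallel to the z axis. The radial
step defaults to min(dx, dy) so no information is lost relative to the
native grid, and columns outside the scan extent are clipped. Bilinear
sampling is exact for intensity fields linear in (x, y), which the tests
exploit as an oracle. En-face images average an odd z window (default 5
planes); at the volume boundary the window center is clamped so the full
window always fits — truncating it would silently change the noise
statistics of the average. No speckle filtering beyond this averaging is
applied.

## Surface reconstruction

Each border (anterior, posterior, optionally flank) is rebuilt in two
passes. Radially, the per-axis marks are interpolated by a cubic
*interpolating* spline with not-a-knot end conditions: the reconstruction is
anchored to the operator's points (they are treated as ground truth, not as
noisy observations to be smoothed), and four points — the allowed minimum —
are exactly the not-a-knot minimum. Angularly, each resampled ring of M
values is interpolated by a periodic cubic spline, which enforces closure
z(0) = z(2π) with a continuous first derivative at the seam. Grid nodes are
taken directly from the radial resampling (the ring interpolant reproduces
them), which makes the surface grid exactly equivariant under rotation of
the annotation set by Δθ.

Marks with non-increasing r are rejected outright rather than sorted: the
(r, z) marking scheme is structurally monotone, so non-monotone input is an
operator or file error. When the innermost mark sits at r > 0 (a vessel
shadow covering the BMO center), the radial curve is continued linearly from
its innermost segment down to r = 0 so the node r_{i0} = 0 exists; such
nodes are flagged *extrapolated* and never enter the thickness average.
Cubic extrapolation was rejected as it can oscillate wildly outside the
data; a linear continuation is the most conservative smooth choice.

Whether the original measurement enforced posterior ≥ anterior is unknown;
crossing grids are reported as warnings at model build (noisy marks near the
flank can legitimately produce small crossings outside the reliable region)
but are a hard error if a crossing node falls inside the region actually
measured.

## Reliable region, thickness, and avgLCT

Thickness is measured along z, not along the surface normal; a plane slab
tilted by α therefore reads t/cos α. The per-axis reliable interval is a
single [r_inner, r_outer] segment; the outer points are closed into a
periodic-spline boundary in the en-face plane, the boundary is extruded
along z, and a node is reliable iff it lies inside the extrusion, within its
axis's interval, and is not an inner extrapolation. Self-intersecting
boundaries are rejected (area would be ill-defined).

avgLCT is the area-weighted mean over reliable nodes with exact
annulus-sector cell areas: cell j on axis i spans [r_j − h/2, r_j + h/2]
clipped to [0, terminal], h = terminal/N, giving weight Δθ·(r_hi² − r_lo²)/2.
The equal-r-section polar grid over-represents the center, so an unweighted
node mean would bias avgLCT toward central thickness; the area-weighted mean
is the defensible reading of "average thickness of the model". The
unweighted mean remains available (`average_thickness(..., weighted=False)`)
for comparison. Curve areas (reliable region, BMO) are computed from the
periodic splines by Green's theorem on a dense parameter grid (4096 samples,
orientation-independent); BMO area reuses the same closed-curve construction
on the per-axis BMO edge marks.

A note on tilt: for a plane slab measured along z, a 5° tilt inflates
thickness by sec 5° − 1 ≈ 0.4%. Claims of ≈ 8% for the same configuration
correspond to tan 5°, not sec 5°; this package follows the plane-slab
geometry, and its tilted-phantom oracle is t·sec α.

## Phantom

The phantom renders a disc-centered LC slab (reflectivity 180) between
analytic anterior/posterior surfaces, prelaminar tissue (110) above,
exponentially decaying signal below, and uniform peripapillary tissue
outside the BMO disc. Shapes: flat; tilted plane (constant perpendicular
thickness, z-gap t·sec α); bowl (paraboloid cupping, deepest centrally);
and a radial-cosine "W" profile (the configuration that motivates dense
marking). The posterior surface is either z-parallel to the anterior or a
flat plane (giving radially varying thickness with a closed-form disc
average, used as a symbolic oracle). Pores are disjoint z-parallel
low-intensity cylinders (rejection-sampled, separation ≥ 2.5 radii) — the
simplest geometry satisfying "small round low-intensity areas in
hyper-scattering tissue". Vessel shadows are z-parallel attenuation columns
along smooth random-walk en-face paths with a Gaussian lateral profile
(FWHM = vessel width), reflecting that their defining property is
continuity across sequential en-face planes. Noise is multiplicative
unit-mean gamma speckle (shape 1/sd²) followed by additive Gaussian read
noise. The phantom is deterministic given its seed.

Default study conditions, chosen once: LC thickness 250 µm; BMO radius
860 µm (aperture ≈ 2.32 mm²); reliable outer fraction 0.67 of the BMO
radius (area ratio ≈ 44.9%, the typical coverage once vessel shadows are
excluded); marking noise scale 8 µm = one axial pixel; 9 marks per axis.
The native grid is 256³; tests and the acceptance script use the 64³
preset with the same physical extent, which leaves the geometry pipeline
unchanged (annotation-driven stages are resolution-independent) while
keeping rendering desk-scale. What the phantom does **not** emulate:
physically realistic OCT speckle statistics and depth-dependent
attenuation, curved Bruch's membrane anatomy, pathology beyond geometry,
and operator marking *bias* (its marks are unbiased noise around truth) —
so passing recovery tests demonstrates correctness of the reconstruction
given marks, not robustness to systematic human error.

Truth-derived annotations place both surfaces' terminals at the BMO radius,
so the anterior and posterior polar grids are aligned; `compute_thickness_map`
requires this alignment and errors otherwise, because nodewise subtraction
across differently spaced grids would be undefined.

The brute-force thickness oracle integrates the analytic z-gap by the
midpoint rule on a 240 × 1400 polar grid (10× the M × N reconstruction
grid) inside the boundary, whose radius-vs-angle profile is resolved from
8192 curve samples (valid for star-shaped boundaries, which all per-axis
constructions are).

## Synthetic cohort

The cohort generator reproduces the three-group structure (normal,
preperimetric, and normal-tension glaucoma, n = 18 each) with per-group
means/SDs for avgLCT, cpRNFLT, MD, age, IOP, refraction and sex ratios.
Within each group, avgLCT, cpRNFLT and MD share a Gaussian copula with
latent correlations 0.35 (avgLCT–cpRNFLT) and 0.30 (avgLCT–MD); combined
with the between-group mean separation, the variance decomposition of the
group parameters puts the pooled avgLCT × cpRNFLT Spearman coefficient at
≈ 0.64. The generator emulates marginal and rank-correlation structure
only — no measurement-error model, no age–thickness dependence.

## Statistics

Kruskal–Wallis, chi-square (no continuity correction) and Spearman delegate
to scipy. Steel–Dwass is implemented directly: for each pair, the
tie-corrected standardized Wilcoxon rank-sum z referred to the studentized
range with k groups and infinite df (q = z·√2 convention); a permutation
mode computes the single-step max-|z| adjustment exhaustively when the
number of group relabelings is ≤ 200 000 (e.g. three groups of 4: 34 650)
and by seeded Monte Carlo otherwise. The asymptotic mode is the default —
standard practice for cohort-scale samples — while the permutation mode is
exact at small n and is what the oracle tests check. "Corrected for age"
partial correlation applies the first-order partial formula to the three
pairwise Spearman coefficients; a rank-residual regression estimator is
exposed as an option (the two agree on elliptical data but the formula
variant is the common reading). ROC analysis enumerates all observed
thresholds; AUC is the tie-corrected normalized Mann–Whitney statistic;
Youden ties resolve to the highest specificity, then the smallest cutoff,
so the reported operating point is deterministic. The ROC orientation
defaults to lower-is-positive (a thinner LC indicates glaucoma), and the
cohort ROC contrasts normal against all glaucoma (PPG + NTG) by default —
the contrast that uses every eye — with the positive set configurable.
Intrasession CV is 100·SD(n−1)/mean per eye; across eyes, per-eye CVs are
pooled by their mean (the most common convention; median/RMS pooling would
differ only in the second decimal at these noise levels).

## Problem sizes and tolerances

Tests and the acceptance script run the reconstruction at M = 24, N = 140
(the method's native resolution — annotation-driven stages are cheap) and
render volumes at the 64³ preset. Recovery tolerances: flat/tilted slabs
±1 µm (interpolation is exact there; the margin covers masking
discretization), curved shapes 2% against the 10×-dense oracle, noisy-marks
bias 2% over 50 seeds. Spline node checks use 1e-6 µm; seam C¹ checks use
finite differences at 1e-7. Degenerate inputs (constant rings, empty masks,
single-class ROC labels, zero marginals) raise informative errors rather
than returning NaN.
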