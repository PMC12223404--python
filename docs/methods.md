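# Methods

## The measurement problem

During transient coronary occlusion, manganese administered intravenously
accumulates in perfused, viable myocardium (Ca²⁺-channel uptake shortens T1
and raises T1-weighted signal) but not in the occluded territory. A dynamic
T1-weighted acquisition spanning occlusion and early reperfusion therefore
encodes the ischemic extent in the per-pixel temporal trend of signal
intensity. This package quantifies that extent two ways (slope criterion
and remote-reference thresholding), measures the companion quantities an
ischemia–reperfusion study reports (LGE area at risk, EDV/ESV/EF, segmental
wall thickening, native T1), and validates every estimator on a phantom
whose truth is known exactly.

## Phantom

**Geometry.** A circular annulus (myocardium) around a circular cavity,
replicated over slices: matrix 120×110×10, FOV 28×25×8 mm³ (voxels
0.233×0.227×0.8 mm). Default radii: endo/epi 1.5/2.5 mm at end-diastole,
0.8/2.2 mm at end-systole — a mouse-sized LV with a 1.0 mm wall thickening
to 1.4 mm in systole, giving an analytic EDV of 56.5 µL and EF of 71.6%,
typical of a healthy animal. The annulus center sits on the voxel center
nearest the grid middle: for an even matrix the exact FOV midpoint is a
voxel *corner*, a degenerate registration in which no sample row passes
through the cavity center and small-cavity voxel counts are biased low;
real anatomy is never grid-aligned, so the generic (center-aligned) case is
simulated. Four 90° sectors (lateral centered at 0°, anterior 90°, septal
180°, inferior 270°) partition the myocardium; the ischemic territory is an
angular sector on the lateral wall whose width sets the true deficit
fraction (width/360 ≈ fraction of annulus voxels).

**Dynamics.** 11 frames over 66 min; timestamps are the midpoints of 11
equal 6-min acquisition intervals (the per-frame duration within the
continuous acquisition is not otherwise constrained, and midpoints are the
natural assignment for a steady-state acquisition). Frames at t ≤ 30 min
are the occlusion (ischemia) window. Perfused myocardium follows a
saturating mono-exponential wash-in SI(t) = s0·(1 + u_max·(1 − e^(−t/τ)))
with s0 = 100, u_max = 1.5, τ = 15 min — a steady uptake that has not
plateaued by 30 min. Ischemic tissue follows SI(t) = s0·(1 − d·min(t, 30))
with d = 0.003/min, a slight decline that freezes at reperfusion. These are
the simplest forms consistent with the observed ROI behavior (monotone
uptake in remote wall; flat-to-declining signal in the occluded territory);
no pharmacokinetic compartment model is implied or needed, because every
downstream estimator uses only signs and thresholds of trends. Cavity and
background hold constant baselines (60 and 5).

**Degradations.** Additive zero-mean Gaussian noise (σ in intensity units;
SNR s means σ = s0/s). Gaussian rather than Rician is the default because at
the simulated SNRs (≥ 40) magnitude-MRI Rician noise is Gaussian to a very
good approximation and Gaussian keeps estimator bias analysis clean; a
Rician option exists. The bias field is the exponential of a fixed zero-mean
in-plane quadratic scaled by `bias_amplitude` — exactly the multiplicative,
low-order smooth shading the correction model assumes. An optional rigid
whole-pixel in-plane shift is applied to post-occlusion frames to mimic
repositioning at balloon deflation; whole-pixel translation avoids
interpolation ambiguity.

**What the phantom does not emulate:** realistic anatomy (papillary
muscles, through-plane obliquity), k-space/gating artifacts, B1
inhomogeneity, partial-volume mixtures at boundaries, motion within a
window, or pharmacokinetics. Passing recovery tests therefore demonstrates
correctness of the estimators under their stated models, not robustness to
every in-vivo confound.

## T1 mapping

The SPGR steady-state closed form is inverted by the standard VFA
linearization (y = S/sin α on x = S/tan α; slope E1, intercept M0(1−E1)).
Voxels with fewer than two positive signals or slope outside (0,1) are
flagged invalid rather than clamped, so failures stay visible in maps. Note
one degenerate case: *constant* signal across angles yields a least-squares
slope just inside 1 and fits as a long-T1 voxel — it is not detectable from
the slope criterion alone. The Gauss–Newton refinement (vectorized, damped
by per-voxel step halving so the residual never increases, T1 clamped to
[100, 10000] ms — outside that window a 7T tissue value is meaningless)
never degrades the linear estimate and reduces noise-driven error. Bias
correction fits a ≤ order-3 polynomial surface to log-intensity per slice
within the mask and divides out the exponentiated, unit-mean-normalized
field; a multiplicative field is identifiable only up to a global scale, so
"recovery" means the corrected/true ratio is spatially constant.

## Perfusion deficit

The slope criterion follows the two-point definition: slope =
(SI_end-of-ischemia − SI_first-frame)/Δt per voxel, with per-voxel OLS over
all occlusion frames as a robustness option (the two agree exactly for
linear trajectories). Deficit = % of myocardial voxels with slope ≤ 0;
"nonpositive" is taken literally, so an exactly flat voxel counts as
deficit. The %LV denominator is myocardium voxels only (cavity excluded),
matching how infarct burden is expressed against tissue; on this phantom's
uniform slice grid, pixel counting and volume weighting coincide. Frames
are not motion-corrected; the window split at t_occlusion (both windows
must be non-empty) is the mechanism that isolates the transition shift.

## Enhancement thresholding

The reference is the septal myocardial ROI (never cavity): sample mean and
SD (n−1). LGE counts voxels strictly above mean + k·SD (ties excluded — a
measure-zero event under noise, and strict inequality makes the noise-free
phantom recover its designed sector exactly). The MEMRI variant applies the
same technique to the end-of-ischemia frame with polarity *below*
mean − k·SD, because by that time the manganese-enhanced remote wall is
bright and the ischemic territory hypo-intense; thresholding above would
measure the healthy wall instead. Both polarities are exposed.

## Volumetrics and wall mechanics

Cavity volume is voxel count × voxel volume summed over slices (Simpson
slice summation on masks), in µL. ED/ES are the frames of maximal/minimal
cavity volume (ties → earliest frame). Wall thickness casts 16 rays per
segment from the cavity centroid, locates endo/epicardial boundaries as
midpoints of the last-inside/first-outside sample pairs at a 0.25-voxel
step (half-voxel accuracy), excludes rays that find no myocardium, and
errors if more than 25% are excluded. Four segments by default (boundaries
at 45°/135°/225°/315°, numbering counterclockwise from the anterior-septal
junction: septal, inferior, lateral, anterior), with a 6-segment
mid-ventricular option. fWT = 100·(WT_ES − WT_ED)/WT_ED per segment. The
cine phantom interpolates radii sinusoidally between ED and ES; an optional
akinetic sector freezes its ED geometry in every frame, which suppresses
lateral thickening the way an infarcted LAD territory does.

## Statistics

Welch's t (Satterthwaite df) for two-group comparisons; degenerate
zero-variance inputs use the convention p = 1 for equal means and p = 0
(flagged) otherwise. Spearman rho is the Pearson correlation of midranks;
p is exact by full enumeration of the n! permutations (tie-adjusted
statistic) for n ≤ 8 — cohort group sizes here are 6–7, so the headline
correlations use exact p — and a t-approximation above. OLS regression
reports the intercept ("offset" between modalities) with a 95% t-interval.
No multiple-testing correction is applied; comparisons are reported
per-pair and labeled.

## Synthetic cohort

7 IRI, 6 sham, 3 naive subjects. IRI true deficit fractions are drawn
uniformly from 15–40 %LV — bracketing the burden range such occlusion
models produce — and the LGE-enhanced sector is 15° wider per side than the
scar sector, encoding the biological fact that the area at risk strictly
contains the eventual scar. That containment, not any tuning, is why the
measured AAR exceeds the scar fraction in every subject and why the
AAR-on-MEMRI regression has a positive offset: the structural signature of
threshold-LGE overestimation. Sham/naive subjects carry no ischemic or
enhanced sector; their nonzero noisy threshold fractions (~2%) reflect the
Gaussian tail beyond 2 SD. Native T1 is 1490 ms (IRI) vs 1487 ms (sham/
naive) with M0 = 1000 and blood T1 2200 ms. Default cohort SNR is 40.
Per-subject seeds derive from the cohort seed via `SeedSequence.spawn`, so
a manifest-identical rerun is byte-identical.

## Problem sizes and numerics

Unit tests run on a reduced 72×66×6 grid at the full in-plane resolution;
recovery and acceptance checks use the full 120×110×10 matrix except the
many-cohort structural analysis, which uses 60×56×6 (the containment and
offset properties are resolution-independent, and 140–700 simulations at
full resolution would add nothing but wall time). The T1 SNR-50 bias check
uses 10⁴ voxels; Welch calibration uses 10⁴ replicates at n = 6 vs 7 with
SDs 1 vs 2. Tolerances in tests come from the quantities' own scales:
voxel-count quanta for fractions, half a voxel for boundary measures, 3%
for cylinder discretization at the full-matrix resolution, 2 percentage
points for EF, 10⁻⁶ relative for noise-free model inversion, 10⁻¹⁰ for
algebraically identical routes.

## Known limitations

- The deficit metrics assume the label map is valid for all frames; a
  shifted phantom without registration displaces the measured territory.
- Ray-cast thickness assumes a star-convex annulus about the cavity
  centroid; strongly remodeled geometries would need contour-based
  measurement.
- The exact-permutation Spearman p is factorial in n and capped at n = 8.
- Rician noise is available but the default analyses assume the Gaussian
  regime; very low SNR would bias the threshold statistics.
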