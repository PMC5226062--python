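# Methods

## Spatial conventions

Voxel indices are 0-based; world coordinates are millimetres in RAS
orientation via each volume's 4×4 affine. All geometry (streamlines,
ROIs, lacunae) lives in world mm. MD is reported in µm²/ms
(1×10⁻³ mm²/s = 1 µm²/ms) so that the clinical decision thresholds
(1.12 and 0.93 µm²/ms) can be used directly; tensors are stored in mm²/s.
The synthetic template grid is 64×64×40 voxels at 1.75 mm isotropic
(close to a typical 1.726×1.726×1.7 mm acquisition), with its affine
centred so the mid-sagittal plane is x = 0 — this makes the left/right
mirror flip an exact voxel-grid reversal.

## Tensor model and fit

The signal model is the single diffusion tensor
S_i = S0·exp(−b_i gᵢᵀ D gᵢ). Multiple b0 volumes are averaged into one S0
estimate, then the six tensor elements are obtained per voxel by ordinary
least squares on y_i = ln S0 − ln S_i = b_i gᵢᵀ D gᵢ. OLS (rather than
WLS/NLLS) is exact on noiseless phantoms and matches long-standing
practice; a weighted variant was deliberately left out of scope. Voxels
with any non-positive signal are flagged invalid and excluded rather than
clamped — clamping would bias MD downward. Eigenvalues are floored at
10⁻⁶ mm²/s so noise cannot push FA outside [0, 1]. FA uses the standard
closed form and is defined as 0 when all eigenvalues vanish.

## Tractography

Deterministic Euler integration of the principal eigenvector field:
x_{k+1} = x_k + h·v(x_k), bidirectionally from each seed, with v
sign-aligned to the previous step. Defaults: step h = 1 mm, angle
threshold 35°, minimum retained length 20 mm. Seeding and stopping FA
thresholds (0.3 / 0.2) follow published automated-fibre-quantification
defaults, since reasonable values are needed and the choice is exposed in
`TrackingParams`. Seeds are placed at every masked voxel centre with
FA ≥ 0.3 (density 1/voxel by default) in deterministic index order, so
identical inputs give identical tractograms.

Direction lookup is nearest-voxel: trilinear interpolation of
eigenvectors is ill-defined across sign flips, and nearest lookup keeps
the geometric oracles (constant and circular analytic fields) exact. When
a step's turning angle exceeds the threshold the final point is kept and
propagation stops, so consecutive points are always exactly h apart.

## Bundle segmentation and profiling

A streamline joins a bundle if it intersects the start and end waypoint
ROI in that order (after orientation canonicalisation); it is clipped
from its first start-ROI crossing to its last end-ROI crossing. ROIs may
be axis-aligned boxes in world mm or binary masks (nearest-voxel
membership). An empty retained set produces an undetected bundle, not an
error, mirroring per-subject tract exclusions in clinical tractometry;
detection counts are reported in the pipeline manifest.

Cleaning iteratively removes streamlines whose length deviates > 4 SD
from the bundle mean or whose mean distance from the core exceeds 5 SD
(≤ 5 iterations) — the published AFQ-style defaults, configurable because
the exact values used in any given study are rarely stated.

Each retained streamline is resampled to 100 nodes equally spaced in arc
length (linear interpolation; endpoints preserved). The core fibre is the
node-wise mean position; node dispersion is the 3×3 position covariance,
regularised with +10⁻⁶ I mm² before inversion. Profile values are
weighted means over member streamlines: Gaussian weights
w ∝ exp(−d²/2) on the Mahalanobis distance from the core (default), or
uniform weights for oracle tests; weights are normalised to 1 at every
node. Scalars are sampled trilinearly; nodes outside the scalar volume
are flagged missing and the profile marked incomplete. Control subjects'
left and right profiles are pooled node-wise; a single detected side is
used alone and flagged.

Node orientation is anchored per tract so that increasing node index
follows increasing ROI number: fornix node 1 at the dorsal extratemporal
end, parahippocampal and uncinate numbering increasing anteriorly. In the
synthetic phantoms this is guaranteed by construction of the centrelines;
for user data it is set by which waypoint is declared the start ROI.

## Group statistics

Profiles are reduced to five ROI means over fixed blocks of 20
consecutive nodes. Contrasts (each patient group vs controls; ILAE 1 vs
ILAE 2+) use Student's pooled-variance two-sample t-test (two-sided;
Welch optional), Cohen's d with pooled SD (positive when the patient
group exceeds the reference), and Benjamini–Hochberg FDR at α = 0.05. The
FDR family pools all tract × laterality × ROI cells of one metric and
comparison pair — one panel set's worth of tests; the family is
configurable because study conventions vary. Section-wise t-profiles
apply the same FDR across the 100 nodes (uncorrected flags available for
display). Clinical contingency tables use the Pearson chi-square without
continuity correction — validated by exact reproduction of the cohort's
published statistics (with Yates' correction the sex statistic would be
4.0, not 5.3); all-zero columns (empty histopathology category) are
dropped first, and a zero margin yields a missing statistic.

## Outcome classification

ROC curves sweep the sorted unique observed values (plus a sentinel),
calling a subject positive at value ≥ threshold (≤ for inverted
classifiers); AUC is the trapezoid under the empirical curve, which
equals Mann–Whitney concordance with ties counted ½ (asserted to 1e-10 in
tests). The combined rule is strictly ">" at both thresholds, as the
decision is defined on the open upper-right quadrant; subjects with a
missing feature (undetected tract) are unclassifiable and excluded from
confusion counts. Report percentages round half away from zero to integer
percent. No cross-validation or confidence intervals are computed — the
thresholds are descriptive cutoffs, not fitted parameters.

## Resection overlap

The per-section resected proportion reuses the profiling weights over a
binary lacuna: node value = Σ_s w_s(i)·1[x_s(i) ∈ lacuna], with
nearest-voxel membership (no partial volume) so constructed fixtures are
exact; the total is the mean over the 100 sections. Group maps rasterise
each bundle (streamlines densified to ≤ half a voxel before voxelisation),
intersect with the lacuna, mirror right-ipsilateral subjects across
x = 0, and average voxel-wise. Spatial normalisation is a precondition —
inputs must already share a template space; the synthetic generator
produces its data directly in that space with an identity transform.

## Synthetic cohorts: what they emulate and what they do not

Profile mode draws, per subject × tract × side × metric, a smooth
baseline curve + a subject-level offset (SD 0.05 µm²/ms MD, 0.03 FA)
+ node-autocorrelated noise (white noise smoothed with a 5-node moving
average, per-node SD 0.05 µm²/ms for MD) + the group shifts in the effect
table. Real subject profiles are smooth, so white node noise would be
unrealistically jagged. The default effect table encodes the qualitative
clinical pattern: shared MD elevation (~0.10–0.12 µm²/ms) along the
uncinate bilaterally, the ipsilateral parahippocampal bundle and the
temporal fornix (ROIs 4–5), and poor-outcome-only elevation in the dorsal
ipsilateral fornix (ROIs 1–3) and contralateral parahippocampal ROIs 1–3,
with small accompanying FA decreases. Baseline MD levels are plausible
white matter values chosen once (fornix ≈ 1.05 µm²/ms, reflecting CSF
partial volume; parahippocampal ≈ 0.9; uncinate ≈ 0.8); no per-tract
absolute baselines were available to copy, so these are stated as
assumptions. They place the clinical thresholds (1.12 / 0.93 µm²/ms)
between the control-like and shifted group means, as in the source
two-feature scatter.

Image mode simulates noiseless (optionally Rician, |S + ε₁ + iε₂|)
single-tensor DWI on the template grid: 60 Fibonacci-sphere directions at
b = 1000 s/mm² plus 6 b0, S0 = 1000. Each tract/hemisphere is a curved
tube (radius 4 mm) whose in-tube voxels carry eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s with the principal axis along the local
tangent; background is isotropic 0.7×10⁻³. Per-subject jitter translates
each centreline by ~1 mm. The analytic centreline, a set of ground-truth
member streamlines and end-waypoint boxes are stored with every phantom
so tracking and core-estimation accuracy are assertable. Image mode
applies MD effects only; FA effects are a profile-mode feature.

Lacunae are ellipsoids over the anterior temporal region whose anterior
(y) half-axis is drawn per group; the group distributions were calibrated
once against the generator's own uncinate geometry so mean resection
proportions approximate 0.42 (seizure-free) vs 0.20 (poor outcome) with
SD near 0.21, and then frozen as defaults.

What passing tests show: the pipeline's machinery — fitting, tracking,
segmentation, profiling, statistics, classification, overlap — is
numerically correct and recovers effects it is told to plant. What they
do not show: robustness to crossing fibres, head motion, eddy currents,
susceptibility distortion, registration error, or real anatomical
variability, none of which the generator simulates.

## Problem sizes used in tests and the acceptance script

Recovery checks use 50 cohorts of 20 subjects/group (profile mode), null
calibration 20 cohorts, large-n sampling oracles 500 subjects/group, the
lacuna calibration 100–200 subjects/group, and image-mode end-to-end runs
1–2 subjects/group on the full grid — sizes chosen to keep every run
desk-scale while leaving comfortable statistical margins.

## Known limitations

* Nearest-voxel direction lookup makes tracks grid-quantised; the
  trilinear-tensor option trades oracle exactness for smoothness.
* The fimbria-fornix waypoint protocol of the original study is not
  public; generic user-supplied waypoint ROIs stand in.
* The FDR family and the t-test variant are conventions, not derivable
  facts; both are configurable and the defaults are stated above.
* Synthetic AUCs and combined-rule operating points depend on the chosen
  effect sizes and noise; they characterise the generator's conditions,
  not any patient population.
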