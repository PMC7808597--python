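# Methods

This note documents the models and procedures implemented in `heartseg`,
the parameter choices that matter, what the synthetic phantom does and does
not emulate, and the numerical decisions a user auditing results should
know about.

## Pipeline

A target image is segmented from a set of atlases (image + heart mask
pairs) in five stages.

**Cropping.** Lungs are segmented by thresholding (default −320 HU),
grouping voxels into six-connected components, discarding components that
touch the lateral borders of the axial slices (exterior air), removing
components below a minimum volume (default 50 cm³) and keeping the largest
one or two. The heart volume of interest (VOI) is the lung bounding box
expanded by a margin (default 10 mm). The lungs flank the mediastinum, so
the box necessarily contains the heart; using the full lung bounding box
rather than a tighter mediastinal box trades some computation for
robustness. Atlas cases are cropped with an extra 15 mm of margin so that,
once rigidly aligned, their support covers the whole target VOI and the
deformable step never sees out-of-support fill near the heart.

**Rigid registration.** Same-modality CT pairs are aligned with a
mean-squared-difference metric (not mutual information — simpler and
adequate within one modality), full sampling, regular-step gradient
descent, and a 3-level multi-resolution pyramid (shrink 4/2/1). Transforms
map points from fixed space into moving space (the resampling convention):
if the moving image is the fixed image resampled with a +d mm translation,
the recovered transform's translation is −d, because resampling the moving
image through it must reproduce the fixed image. A rim of the fixed grid
(default 10 mm) is excluded from the metric: voxels sampled outside an
image's support are filled with air (−1000 HU), and near the grid border
that fill otherwise biases recovered translations by around a millimetre —
with the rim excluded, known transforms on the default phantom are
recovered to ~0.02 mm.

**Demons registration.** Classic Thirion demons: per-voxel update
`u = (m − f)∇f / (‖∇f‖² + (m − f)²)` (zero where the denominator
vanishes), with the accumulated displacement field smoothed by a Gaussian
after every iteration (diffusion-like regularisation; an update-field
variant would be the fluid-like alternative and is not the default), run
coarse-to-fine over the same pyramid. The moving image is first resampled
onto the fixed grid through the rigid transform; demons solves for the
residual field and the rigid part is composed back analytically, so the
returned field is the complete fixed-to-moving map. The per-level solver is
ITK's demons filter; this package owns the schedule, conventions and
provenance. Each registration logs the mean-squared difference before and
after (evaluated on the finest-level smoothed images, restricted to where
the warped moving image has support); a final metric more than 5% above the
initial one raises an error, with an absolute floor of
`1e-4·(dynamic range)²` so that near-perfect initial alignments are not
flagged over interpolation residuals.

**Atlas selection.** The propagated masks are combined by strict-majority
vote (ties to background) into a consensus delineation; each atlas's
deviation is its MASD to that consensus (an empty warped mask scores
infinite deviation). Atlases above `median + 1.5·IQR` of the deviation
distribution are rejected; if that would leave fewer than `min_retained`
(default 3), the lowest-deviation atlases are kept instead. The rule is a
standard robust outlier fence — with equal deviations the IQR is zero and
nothing exceeds the median, so nothing is rejected. Every decision is
logged with its score and the fence value.

**Label fusion.** Fused probability
`p(v) = Σᵢ wᵢ(v)·mᵢ(v) / Σᵢ wᵢ(v)` with weights
`wᵢ(v) = 1/(ε + local mean |target − warped atlasᵢ|)` over a cubic patch of
radius 5 mm (ε = 1 HU keeps weights finite; patches are clipped at the grid
boundary and average only existing voxels). The heart contour is the
`p ≥ 0.5` superlevel set; with equal weights this reduces exactly to
majority voting with ties labelled foreground. The probability map is
invariant to atlas order and monotone in each atlas's vote.

**4D propagation and PRV.** The 0%-phase contour is carried to each other
phase by one intra-patient demons registration — identity-initialised, no
rigid step, since all phases share the scanner frame — registering 0%
directly to each phase (star topology; chaining adjacent phases would
accumulate error). The PRV is the voxelwise union of the per-phase masks on
the phase-0 grid, hence a strict superset of each. Propagation costs one
fusion plus nine registrations per study; the alternative `independent`
mode runs the full multi-atlas machinery on every phase (ten fusions) and
is provided for comparison.

## Metrics

Surfaces are the centres of mask voxels with at least one six-connected
background neighbour (grid boundaries count as background) — deterministic
and directly checkable against a brute-force scan, unlike mesh extraction.
Nearest-surface distances use an exact Euclidean distance transform on the
physical grid; the test suite checks equivalence with the exhaustive
pairwise computation to 1e-9. MASD averages the two directed mean
distances (conventions differ in the literature; the alternative pools both
surfaces' points, which differs at below-voxel scale). HD is the maximum of
the two directed maxima, so MASD ≤ HD always. Cohort tables report
mean ± sample sd (n−1; a single observation reports sd 0), one row per
phase, a pooled all-phases row, and a PRV row when supplied.

## The phantom

Each synthetic patient is an elliptic-cylinder body (40 HU) with two lung
ellipsoids (−750 HU) and a heart ellipsoid (45 HU) carving the mediastinum,
plus additive Gaussian noise (sd 10 HU), on a 64³ grid at 2.5 mm isotropic
spacing. The 5 HU heart/body step under 10 HU noise is deliberate: the
difficulty of the heart boundary on non-contrast CT is the crux of the
task, and a high-contrast phantom would trivialise it. The grid is
desk-scale — clinical scans have ~1.5 mm slices and much larger matrices —
so absolute surface distances here are on a coarser lattice than clinical
reports. In-plane clinical resolution is not claimed or emulated.

Cohorts perturb every radius by a fractional Gaussian (default sd 8%,
within the 5–10% range of reported inter-patient cardiac size variability)
and every centre by the same fraction of the corresponding radius, with
rejection-resampling against the anatomical invariants (heart between the
lungs and inside the body; lungs separated from exterior air by a chest
wall). Each member gets its own noise realisation; a zero-variation cohort
reproduces the base phantom exactly.

A 4D study displaces the heart inferiorly (plus a 30% anterior share) along
the cosine trace `a·(1 − cos 2πp/n)/2`, with phase 0 fixed at full exhale
(4D-CT binning conventions differ on whether 0% is end-inhale or
end-exhale; one had to be chosen and documented). Lung floors follow the
diaphragm (inferior edge down by the full displacement, apex fixed). Phases
are regenerated analytically from the displaced geometry rather than by
warping voxels, so per-phase ground truth is an exact voxelisation; the
noise realisation is shared across phases of one study, making the
amplitude-0 study bit-identical across phases. Default amplitude 10 mm,
within the up-to-13 mm displacement reported for the heart under
respiration. Cardiac-cycle (heartbeat) motion and imaging artefacts are
not modelled: clinical 4D-CT of this kind is not cardiac-gated, and
artefact robustness is outside what passing these tests can show. Passing
on the phantom demonstrates the machinery is correct and well-behaved under
realistic geometry, contrast, noise and motion — not clinical performance.

## Key parameters

| Parameter | Default | Why |
| --- | --- | --- |
| Lung threshold | −320 HU | standard CT lung thresholding range |
| Minimum lung component | 50 cm³ | excludes airway/noise fragments |
| VOI margin | 10 mm | contains the heart with room for motion |
| Pyramid | shrink 4/2/1, smooth 6/4/3.5 mm | capture range vs detail; the heavy fine-level smoothing is what makes the 5 HU heart boundary usable under 10 HU noise |
| Demons iterations / level | 80 | convergence plateau on 64³ recovery tasks |
| Field smoothing σ | 2.5 mm | smoothness/fidelity balance; larger values visibly under-track 10 mm motion because per-iteration field smoothing decays large displacements |
| Rejection fence | median + 1.5·IQR, keep ≥ 3 | standard robust outlier rule |
| Patch radius / ε | 5 mm / 1 HU | local-error weighting scale |
| Probability threshold | 0.5 | weighted-majority reduction |

All registration numbers are desk-scale choices for ~64³ volumes at 2.5 mm
and are exposed in `RegistrationConfig`; clinical-resolution use would need
its own schedule.

## Numerical choices and degenerate inputs

Voxel indices are 0-based with half-open boxes `[lo, hi)`; physical points
follow the NIfTI/ITK convention `origin + direction·(index∘spacing)`, all
distances in mm. Out-of-support resampling fills −1000 HU for images and 0
for masks (CT-plausible padding keeps registration stable near crop
borders). Masks are warped by linear interpolation of the indicator
followed by a 0.5 threshold — smoother propagated contours than
nearest-neighbour warping. DSC of two empty masks, surfaces of empty masks,
and bounding boxes of empty masks are errors, not conventions. Consensus
ties (exactly half the votes) resolve to background; the fusion threshold
uses ≥. Registration is deterministic for fixed inputs and configuration;
cohort generation and experiments are reproducible from explicit integer
seeds.

## Known limitations

- Mid-cycle phases of a 10 mm-amplitude study are tracked with centroid
  errors up to ~3 mm (DSC ≈ 0.92): at full inhale the low-contrast
  superior/inferior heart boundary gives demons little signal to hold onto.
  Quarter-cycle phases track within 2 mm.
- A single propagated atlas reaches DSC ≈ 0.85–0.90 against the target
  truth; the headline accuracy comes from fusion, as intended.
- The rejection fence assumes most atlases are concordant; a majority of
  discordant atlases would corrupt the consensus itself.
- Symmetric/diffeomorphic demons variants, B-spline/affine alternatives,
  inverse-field computation and DICOM(-RT) I/O are out of scope.
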