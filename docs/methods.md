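# Methods

This note documents the models, numerical choices and limitations behind
`mousepet`. It is the companion to the README's overview.

## Coordinate conventions

All volumes are canonicalized on load to a fixed right-handed index order
matching the Allen CCF: axis 0 posterior, axis 1 inferior, axis 2 right
(P/I/R). World coordinates are millimetres in the same frame; a voxel's
world position is its centre. Only axis-aligned geometries are supported —
an oblique or sheared affine raises a geometry error rather than being
silently resampled. Two bounding boxes recur: the native atlas box
(13.2 × 8.0 × 11.4 mm in P/I/R order) and an extended working box
(16.1 × 9.6 × 12.1 mm) that leaves room for the skull and extra-cerebral
soft tissue the CT pipeline needs. Atlas-space work uses 0.1 mm voxels;
templates and normalization use 0.2 mm.

## VOI atlas construction

A VOI specification names, for each region, the ontology subtree roots
(acronyms or ids), and whether the region is bilateral or central. The
builder collects each root with all descendants, masks the annotation
volume, restricts bilateral regions to a hemisphere (the midplane of the
ML axis; with an odd ML dimension the central column belongs to neither
side), erodes with a 6-connected one-voxel erosion (26-connectivity is a
config knob), and rejects regions below 1.5 mm³ post-erosion — small
regions are unreliable at PET resolution. Splitting precedes erosion, so
bilateral VOIs are also eroded at the midline face. Specs are applied in
order; a voxel already labelled is never relabelled, and overlaps are
logged as spec errors. The packaged default spec (12 bilateral + 3 central
= 27 regions) maps region names to ontology acronyms; groupings that names
leave open (hindbrain = pons + medulla; hippocampal region = HIP, not the
wider formation) live in the editable YAML, not in code.

## Registration

**Rigid stage.** Six-parameter pose (translation + intrinsic-XYZ Euler
angles about the fixed volume's centre), optimized by Powell descent over
a smoothing/resolution pyramid — (0.8 mm grid, 1.2 mm FWHM), (0.4, 0.6),
(0.2, 0.3) by default — with an intensity-centroid initialization. The
metric is SSD intra-modality or a 32-bin Parzen-smoothed mutual
information across modalities. Powell is derivative-free and, with fixed
initialization, fully deterministic.

**Elastic stage.** Each displacement component is a separable cosine
series over the fixed volume's physical box; default orders (5, 4, 4)
give shortest basis wavelengths of ≈ 6 mm per axis — deliberately
low-frequency, since the anatomy-scale differences between healthy adult
mice are smooth. The objective is the mean squared intensity residual
(with an optional closed-form global intensity scale) plus λ times a
membrane energy, diagonal in coefficient space with weight
Σ_axis (πk/L)² per coefficient. Gauss–Newton steps with Levenberg damping
and step rejection guarantee a non-increasing objective; a vanishing
proposed step is treated as convergence, while persistent rejection flags
the field `converged=False` and returns the best iterate. λ = 0.05 and
the two-level elastic pyramid (0.8, 0.4 mm) were calibrated on the
phantom; no published hyper-parameters exist for this stage. Note the
membrane penalty's null space is a bulk translation: as λ → ∞ the field
collapses to the best constant shift, not to zero.

**Conventions.** Fields store pull-back displacements on the template
grid (template point x′ ↔ subject point x′ + d(x′)); rigid maps compose
on the outside, `x_subject = R(x′ + d(x′))`. Composition is evaluated
analytically where coefficients are available and by linear interpolation
otherwise; numeric inversion uses damped fixed-point iteration, which
converges for the small, smooth fields produced here.

## Template building

Two stages, no further iteration: (1) every MR is registered
(rigid + elastic) to an atlas-space reference and averaged; (2) every MR
is re-registered intra-modality to that stage-1 mean, the warped MRs are
averaged into the final MR template, and each subject's total deformation
(MR elastic composed with the MR→scanner rigid link) warps the
co-registered CT and PET onto the same grid to form the CT and PET
templates. PET contributions are scaled to their own global mean before
averaging so dose differences cancel. Subjects whose elastic stage fails
to converge are excluded and reported; per-subject final SSD and field
statistics are logged as quantitative QC in place of expert visual
review.

## Displacement validation

For one subject normalized by two pipelines, the per-voxel displacement is
the Euclidean distance between the two mapped subject-space points,
‖d_CT(x′) − d_MR(x′)‖ mm. Aggregation is a true RMS — over subjects per
voxel, and pooled over voxels × subjects per region
(√(Σ‖Δ‖²/(N·V))). A literal sum-of-roots variant (no 1/N, no outer
root) exists behind `aggregate="sum_root"` purely for comparing against
legacy tabulations; it is not an RMS. Whether regional values should pool
before or after the root is genuinely ambiguous in this field; pooling
before the root was chosen as the single well-defined RMS.

## Quantification and statistics

SUV = concentration / (injected activity / body weight), density
1 g/mL. Global-mean scaling divides by the mean over the union of all
atlas labels — the only brain definition the toolbox owns — computed
after warping to template space. Because SUV conversion is a positive
constant per image, it cancels under scaling; this identity is verified
numerically in the tests. Regional means feed a two-tailed paired
Student's t (df = n−1); all-equal differences are handled explicitly
(t = 0, p = 1 if the common difference is zero; p = 0 with a degeneracy
warning otherwise). BH FDR at q = 0.05 is applied across the region set
(one-tailed testing and other q are config options). Caveat: with a
strong focal effect, global-mean scaling depresses all other regions'
scaled means, and a two-tailed test will flag those decreases — interpret
signs, not just flags.

## The phantom

The synthetic head is an analytic model: an ellipsoidal brain (semi-axes
4.8 × 2.6 × 4.2 mm — inside the native atlas box) partitioned into
mirror-symmetric internal regions as Voronoi cells of named seeds (four
bilateral pairs loosely placed as cortex / dorsal striatum / thalamus /
hypothalamus, two central as midbrain / hindbrain), a skull shell carrying
bony landmarks (snout ridge, occipital ridge, tympanic bullae — without
them an ellipsoidal shell leaves tangential displacement modes invisible
to CT, unlike any real skull), and soft tissue out to 1.25× the brain so
the posed head stays inside the extended box. Subjects are drawn with a
bounded rigid pose (±0.8 mm, ±4°) and a random low-order cosine field
rescaled to an exact peak amplitude (default 0.5 mm, the scale of
pipeline disagreement the method is meant to resolve); the recorded
(rigid, field) pair is exactly the pull-back mapping a perfect
registration would return, because subjects are rendered by classifying
each voxel's sub-voxel samples at the analytically inverted mapping.

Rendering integrates 2³ analytic sub-voxel classifications per voxel
(partial-volume integration, as scanners do), then: CT at 0.2 mm with a
bright skull, 0.3 mm PSF and additive Gaussian noise (σ = 3 against a
40/800 soft/bone contrast); MR at 0.15 mm with per-region soft-tissue
contrast and dark skull; PET at 0.4 mm smoothed with a 0.8 mm FWHM
isotropic PSF and Gaussian noise with variance proportional to intensity
— a post-reconstruction surrogate for count statistics, since the toolbox
consumes reconstructed images. Paired cohorts share each subject's
anatomical deformation across both conditions, draw imaging noise and a
5% per-region multiplicative biological variability independently per
condition, and multiply d7 uptake by (1 + effect) in designated regions.
Dose and weight are drawn near 4.7 MBq and 27 g.

What the phantom does **not** emulate: real skull/brain anatomy, CT beam
hardening and scatter, PET attenuation, randoms, or reconstruction
artifacts, intensity non-uniformity in MR, and anatomy outside the head.
Passing tests therefore demonstrate correctness and calibration of the
algorithms under a controlled, realistic-scale geometry — not performance
on any particular scanner's data.

## Problem sizes and determinism

The shipped studies run at 0.2 mm working resolution in the extended box
(81 × 48 × 61 voxels): the pipeline-agreement study uses n = 6 subjects at
0.5 mm deformation amplitude; statistical calibration uses 50
effect-cohort and 200 null-cohort replicates generated in template space,
isolating the statistics from registration. The stage-1 atlas resolution
default remains 0.1 mm for real data. Every random draw flows from a
single integer seed through one generator per operation; the optimizers
contain no randomness, so identical inputs and settings reproduce results
bit-for-bit.

## Known limitations

- The elastic model is intentionally low-frequency; pathology-scale or
  surgical deformations are out of scope, as are diffeomorphic guarantees.
- MI is available for the rigid stage only; elastic registration assumes
  comparable contrast after global intensity scaling.
- NRRD support covers the subset used by the Allen distribution (raw/gzip,
  axis-aligned); NIfTI is the native format. No DICOM.
- Hemisphere splitting assumes the annotation is mirror-symmetric about
  its ML midplane, as CCFv3 is by construction.
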