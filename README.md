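# mousepet

A toolbox for quantitative mouse PET–CT brain imaging that does not require
MR. It builds a volume-of-interest (VOI) atlas in the Allen Common
Coordinate Framework (CCFv3) from the hierarchical structure ontology,
spatially normalizes subjects into that space using **only the CT image**
(rigid + low-frequency elastic registration), validates the CT-based
pipeline against an MR-based gold standard with a deformation-displacement
metric, and quantifies regional tracer uptake with paired-sample statistics
and Benjamini–Hochberg FDR control.

Intended users: preclinical imaging groups analyzing mouse PET–CT studies
(e.g. test–retest designs in disease models) who want CCF-compatible
regional statistics without acquiring a high-resolution 3-D MR per animal.

## The core methods

**Atlas construction.** Each VOI is the union of one or more ontology
subtrees ("every substructure" of a named root), optionally split at the
mediolateral midline into left/right, then regularized by a one-voxel
morphological erosion; regions smaller than 1.5 mm³ (small against PET
resolution) are rejected. The default specification ships 12 bilateral +
3 central entries → 27 regions.

**Spatial normalization.** A rigid stage (Powell descent over a smoothing
pyramid; SSD or mutual information) followed by an elastic stage that
parameterizes each displacement component in a separable 3-D cosine basis
over the field of view and minimizes

    E(c) = mean_v [ s·M(x_v + d_c(x_v)) − F(x_v) ]² + λ·cᵀLc

by Gauss–Newton with Levenberg damping (L: diagonal membrane-energy
penalty, s: optional global intensity scale). Fields store pull-back
displacements on the template grid: a template point x′ corresponds to the
subject point x = x′ + d(x′).

**Pipeline validation.** For a subject normalized with both the CT and the
MR pipeline, the per-voxel displacement between the two mappings is
‖d_CT(x′) − d_MR(x′)‖; it is pooled as a root-mean-square over subjects and
voxels per region.

**Quantification.** PET volumes are converted to standardized uptake values
SUV = C / (injected activity / body weight), scaled to the cerebral global
mean (mean over the union of atlas VOIs), reduced to regional means, and
compared between paired conditions with Student's t for paired samples;
regional p-values receive Benjamini–Hochberg FDR adjustment.

**Synthetic phantom.** A seeded generator produces CT/MR/PET triplets of an
analytic mouse head (ellipsoidal brain partitioned into mirror-symmetric
Voronoi regions, skull shell with bony landmarks, extra-cerebral soft
tissue) under known rigid poses and smooth ground-truth deformations, plus
paired cohorts with injected regional uptake effects — so every stage is
testable against exact ground truth without downloads.

## Worked example

```bash
mousepet simulate --out study/ --seed 5 --n-subjects 6 --effect STRd=0.2
mousepet quantify --manifest study/manifest.csv --atlas study/atlas.nii.gz \
    --regions study/atlas_regions.csv --out study/stats/
```

The first command writes a paired d0/d7 cohort (PET + CT NIfTI volumes, a
manifest CSV with injected activities and body weights) with a +20% uptake
effect in the dorsal-striatum-like region, plus the phantom's VOI atlas.
The second runs SUV conversion, global-mean scaling, regional extraction
and paired statistics, printing:

```
8 region(s) significant after FDR at q=0.05
```

In `study/stats/regional_stats.csv` the two dorsal-striatum rows carry the
strongest signal (scaled means 1.061 → 1.198, adjusted p ≈ 0.004,
direction positive). The other flagged rows are *decreases*: in this
phantom the affected region is a large fraction of the brain, so the +20%
focal increase inflates the global mean and depresses every other
globally-scaled regional mean — the classic spillover behaviour of
global-mean normalization, which a two-tailed test then detects. Interpret
directionality, not just significance flags.

The pipeline-agreement study (CT vs MR normalization on a deformed noisy
cohort) is available as:

```bash
mousepet validate --out validation/ --seed 1 --n-subjects 6
```

which writes the per-region RMS displacement table and prints the average.

## Using real Allen CCF data

`mousepet build-atlas` accepts the Allen CCFv3 annotation volume (NRRD or
NIfTI, e.g. the 100 µm `annotation/ccf_2017` release), the ontology JSON
from the Allen "Atlas Drawings and Ontologies" API, and an optional YAML
VOI spec (defaults to the packaged 27-region set). Downloads are left to
the user; nothing in the test suite requires network access.
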