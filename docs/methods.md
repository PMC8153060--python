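# Methods

## Problem and model

The dorsal claustrum is a 1–2 voxel thick gray-matter sheet between the
putamen and the insular cortex. Its segmentation here is purely geometric
and intensity-based, resting on three anatomical premises: (i) the claustrum
lies strictly lateral to the putamen's lateral face, within ~5 mm; (ii) the
insular cortex, whose T1w intensity resembles the claustrum's, is hugged by
sulcal CSF, so excluding a CSF neighborhood excludes the insula; (iii)
between putamen and insula the only tissues are claustrum gray matter and
the brighter extreme/external-capsule white matter, so a two-class
intensity split separates them. The ventral claustrum (fragmented) and the
thin anterior–superior segment bending over the insula are outside the
method's reach by construction: the ROI is anchored to the putamen's
ventral–dorsal extent.

All volumes are reoriented on read to a fixed convention (first axis
left→right, second posterior→anterior, third inferior→superior) so
"lateral" is a signed direction along the first array axis; masks are
matched to volumes by shape and spacing (tolerance 1e-3 mm), with spatial
registration assumed upstream.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `expansion_mm` | 5 | mm | lateral ROI depth beyond the putamen edge; converted to `round(5/dx)` voxels (7 at 0.7 mm) |
| `csf_margin_voxels` | 5 | voxels | inclusive Euclidean exclusion radius around CSF |
| `k` | 2 | — | number of intensity classes (gray vs white); fixed |
| `smooth_sigma_voxels` | 1.0 | voxels | in-sagittal-plane Gaussian width, truncated at 3σ |
| `smooth_threshold` | 0.25 | — | re-binarization level after smoothing |
| `min_explained_variance` | 0.75 | — | quality gate on the intensity split |
| mask binarization | 0.5 | — | inclusive threshold for probabilistic inputs |

Openly underdetermined choices, decided as follows:

- **Edge definition.** "Lateral edge" is implemented as one voxel per
  (PA, IS) column — the extreme lateral index. This is the simplest reading
  that makes a purely lateral expansion well defined.
- **ROI excludes the putamen.** The claustrum lies *between* putamen and
  insula, so the ROI starts one voxel lateral to the edge; this guarantees
  final ∩ putamen = ∅ by construction.
- **CSF margin metric.** Euclidean distance in voxel units, inclusive
  (≤ 5), computed with an exact distance transform. Chebyshev distance is a
  plausible alternative; Euclidean was chosen as the less aggressive and
  more isotropic exclusion.
- **Exact 1-D clustering.** In one dimension with two classes, the optimal
  within-cluster-sum-of-squares partition is a contiguous split of the
  sorted values; it is found exactly by a prefix-sum scan over all n−1
  splits (ties broken toward the smaller lower cluster). This replaces
  iterative Lloyd refinement, which is only locally optimal and needs an
  initialization convention; the exact solver is deterministic, and tests
  verify it against an independent naive scan.
- **Smoothing kernel and threshold.** Unspecified by the anatomy; chosen as
  Gaussian σ = 1 voxel per sagittal slice, re-binarized at ≥ 0.25. The
  derivation: an isolated voxel's central response is w₀² ≈ 0.16 (removed —
  speckle suppression), a 1-voxel-thick in-plane line retains w₀ ≈ 0.40
  (preserved — the sheet survives). Smoothing never crosses the left→right
  axis, so the sheet is not diluted laterally and the whole pipeline is
  exactly equivariant under mirroring (a flip permutes sagittal slices
  without changing any per-slice arithmetic).
- **Unimodality gate.** If the ROI contains no gray/white mixture (e.g. no
  claustrum, or a blood vessel destroying the contrast), a two-class split
  still "succeeds" numerically by halving the noise at its mean. The split
  of a unimodal Gaussian explains at most 1 − 2/π ≈ 0.64 of the variance,
  whereas a genuine bimodal gray/white mixture at realistic contrast
  explains > 0.9; below `min_explained_variance` = 0.75 the segmentation is
  declared empty with a warning. Exactly constant intensities are an error
  (`degenerate intensity distribution`) rather than an empty result.
- **Bilateral inputs.** A bilateral putamen mask is split into connected
  components assigned left/right by centroid relative to the volume
  midplane; hemispheres are processed independently.

## Measures

Volume is voxel count × voxel volume (0.343 mm³ at 0.7 mm isotropic). The
T1w/T2w ratio divides co-registered images voxelwise (NaN where T2w ≤ 0),
cancelling shared multiplicative biases; regional values are volumetric
mask means (a cortical mid-thickness surface sampling is *not* performed —
regional means here are an approximation of that convention, not an
equivalence). MD comes from a per-voxel log-linear least-squares fit of
ln S = ln S₀ − b gᵀ D g (≥ 1 b=0 volume, ≥ 6 non-collinear directions,
full-rank design required); MD = trace(D)/3. Negative MD is reported and
flagged, not clamped, so downstream QC can exclude affected subjects. The
fit is deliberately the plain log-linear estimator: deterministic and
testable against the closed-form forward model; weighted/robust variants
and other tensor metrics (FA, eigenvectors) are out of scope.

Dice on two empty masks is an error, not a convention: silent 0-or-1
definitions hide upstream failures.

## Covariance analysis

Each subject's row of regional values is z-scored across regions
(sample, n−1, standard deviation; constant rows are an error naming the
subject). Row standardization removes per-subject additive and
multiplicative biases exactly; since Pearson r is affine-invariant per
column, its entire effect on the network is this bias removal. The seed's
column is excluded from its own network; the contralateral homologue is an
ordinary target. Missing values are handled pairwise-complete with the
effective n reported; fewer than 3 complete pairs gives r = NaN.

Correction is Bonferroni by default (significant ⇔ p < α/n_tests), the
strictest defensible reading of "corrected", with Benjamini–Hochberg
exposed as an alternative. The family size defaults to
2 hemispheres × (target regions) × (3 measures), computed from the actual
table dimensions and recorded in the output sidecar rather than hard-coded.

One caveat of row z-scoring with p regions: it induces an expected
correlation of −1/(p−1) between null columns and slightly attenuates true
correlations (a planted ρ = 0.6 among 80 regions is recovered as ≈ 0.59;
among 20 regions, ≈ 0.55). At the 80-region design this is negligible, but
analyses with few regions should prefer raw correlations or account for
the attenuation.

## Phantom and cohort generators

The phantom emulates exactly the features the algorithm relies on, at
0.7 mm isotropic on a 96³ grid: an ellipsoidal putamen (convex lateral
face); the truth claustrum as an offset surface of that face at a smoothly
varying 1.5–3.5 mm lateral offset, 1–2 voxels thick, restricted to the
face interior, with ~3 "puddle" widenings protruding laterally; an insular
band 8–10 voxels lateral of the face; a CSF band at 11–12 voxels following
it. T1w means are CSF 30 < gray 70 < putamen 75 < white 110 (a.u.),
additive Gaussian noise σ = 5 per channel — a gray/white separation
comparable to good T1w contrast, challenging but solvable for the split.
T2w inverts the contrast. A left-hemisphere phantom is produced by
mirroring the right-hemisphere arrays (noise included), making mirror
invariance exact. Deliberately absent: realistic whole-brain anatomy, bias
fields, partial-volume mixing at tissue borders, motion/EPI artifacts —
so passing recovery tests demonstrates the geometric and intensity logic,
not robustness to real-scanner confounds. Typical recovery on default
phantoms is Dice ≈ 0.8 with a ≥ 0.7 floor across seeds; the residual
mismatch is dominated by smoothing-induced one-voxel dilation of the sheet
and by puddle tips clipped by the CSF margin, mimicking the false-positive/
false-negative border behavior seen with real data.

Cohorts are drawn from a multivariate normal with a planted correlation
matrix (eigendecomposition square root, so semi-definite designs are
allowed), optionally scaled per subject by a log-normal bias — the nuisance
z-scoring must remove. Defaults mirror the reference design: 80 regions
(40 per hemisphere), with n = 500 subjects for recovery checks and 200
repetitions of 30-subject null cohorts for calibration; these sizes keep
the full suite fast while leaving sampling error well inside the asserted
tolerances.

## Known limitations

- Ventral and anterior–superior claustrum are not segmented (by design).
- Regional T1w/T2w and MD are volumetric-mask means; no surface sampling.
- The putamen and CSF masks are consumed as given: errors there propagate
  directly into the ROI (the dominant failure mode with real data).
- The unimodality gate's 0.75 threshold separates the unimodal ceiling
  (~0.64) from realistic bimodal contrast (>0.9); very low-contrast
  acquisitions could fall between and be rejected.
- No gradient-nonlinearity correction or any DWI preprocessing: signals
  are fit as provided.
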