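# Methods

## Fingerprint model

A subject's neural fingerprint is a 20-element vector of target/mirror
mean-intensity ratios, one per diffusion-weighted gradient of a fixed
21-volume scheme (1 × b=0, 20 × b=1000 s/mm²). The mirror ROI is the
target reflected across the midsagittal plane, taken to be the grid
midplane of axis 0: the package assumes inputs are co-registered to a
left–right symmetric template space, with 0-based voxel indices and
axis 0 as the left–right axis. The b=0 volume is excluded from the
fingerprint (20 elements against 20 gradients). The ratio uses the
arithmetic mean over mask voxels, so the fingerprint is invariant to any
global intensity gain and maps r → 1/r under target/mirror exchange.
Clustering operates on the raw 20-vectors; no principal-component
reduction is applied anywhere in the pipeline.

The gradient *directions* never enter the fingerprint arithmetic — only
their constancy of ordering across subjects matters. The default scheme
draws 20 pseudo-random unit directions once from a fixed named seed and
ships them as package state, so every cohort shares one ordering.

## Synthetic phantom

The phantom exists so that every stage is testable without any external
data. Its defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| grid | 48×48×20 voxels at 1×1×5 mm | clinical in-plane resolution and slice thickness at desk scale |
| base MD | 0.8×10⁻³ mm²/s | healthy-tissue mean diffusivity |
| base FA | 0.30 | mild anisotropy, principal axis inferior–superior |
| acute `adc_scale` | 0.6 | reduced ADC → hyperintense DWI lesion |
| sequela `adc_scale` | 1.8 | raised ADC → hypointense DWI lesion |
| lesion `fa_scale` | 0.7 | anisotropy loss inside lesions |
| lesion radius | 6 mm | single spherical lesion, center jittered per subject within the left hemisphere |
| s0 / noise | 1000 / σ = 2% of s0 | Rician magnitude noise, visible but not dominant |
| cohort | 8 normal / 8 acute / 3 sequela | three-class design with unequal class sizes |

The brain is an axis-0 symmetric ellipsoid of homogeneous prolate
tensors; with the principal axis along z the field is exactly invariant
under the mirror reflection, so noiseless lesion-free fingerprints are
identically 1 — the sharpest possible oracle for the ratio arithmetic.
Given mean diffusivity m and fractional anisotropy f, the prolate
eigenvalues are λ₁ = m(1+2δ), λ₂ = λ₃ = m(1−δ) with
δ = f / √(3 − 2f²), which makes lesion insertion an exact rescaling of
(m, f) per voxel. Signals follow the single-tensor model
S = s0·exp(−b gᵀDg); Rician noise replaces S by √((S+n₁)² + n₂²).

What the phantom does **not** emulate: anatomy (gyri, CSF, white-matter
tracts), partial-volume effects, EPI distortion, motion, registration
error, multi-focal or cortical lesions, and between-subject anatomical
variability. Passing tests therefore demonstrate the correctness of the
algorithmic chain under its stated assumptions — symmetric brains,
single well-separated spherical lesions — not clinical performance.

## ROI strategies

**Manual.** Rater masks are combined by voxelwise intersection (an empty
intersection is an error signalling rater disagreement). Normal
subjects, having no lesion, receive one hemisphere (left, by convention)
as target; its mirror is the right hemisphere and the resulting
fingerprint sits near unity. The same convention is the fallback for the
other two strategies when they find no lesion.

**Semiautomatic.** Per subject, the 20 diffusion-weighted volumes are
averaged into one image and each brain voxel is compared with its
mirror: d(v) = I(v) − I(mirror(v)). One reference subject per class
contributes the d-values inside its target ROI; the three empirical
distributions are smoothed by Gaussian KDE with Silverman's bandwidth
and the two thresholds are the density crossings (sequela↔normal gives
t1 < 0, normal↔acute gives t2 > 0), each searched between the two class
means and falling back, with a warning, to the midpoint of the means if
no crossing exists. At inference, candidates are {d > t2} (acute-like)
and {d < t1} (sequela-like); the set with the larger summed |d| wins —
lesion laterality metadata is not assumed available — and the returned
ROI is its largest 26-connected component, ties broken by larger summed
|d| for determinism. The signed two-sided rule (rather than |d|
thresholding) is a deliberate design choice: it preserves the direction
of the asymmetry, which is what distinguishes acute from sequela.

**Automatic.** Diffusion tensors are fitted per voxel by log-linear
least squares on ln(S_i/S0) = −b g_iᵀDg_i (≥ 6 directions and one b=0
volume required; voxels with non-positive signal are skipped; negative
eigenvalues are clipped to zero), FA is computed from the eigenvalues,
and the group-level target ROI is the set of voxels where patients' FA
is significantly lower than controls' by a one-sided Welch t-test at
uncorrected P < 0.005. This is a deliberately simplified, self-contained
voxelwise comparison — no FA skeletonization, nonmaximum suppression or
skeleton projection — keeping the decision rule (uncorrected P < 0.005,
FA decrease) while dropping the external registration/skeleton
machinery. Voxels with zero variance in both groups are excluded from
testing.

## Clustering

Lloyd k-means with greedy farthest-point seeding from a seeded start
plus 100 random restarts (the cohorts are tiny, so near-exhaustive
coverage is cheap; tests verify the global optimum is reached on n ≤ 10
against exhaustive partition enumeration). Under the Euclidean metric
the objective is the within-cluster sum of squares and centroids are
arithmetic means. Under the cosine metric a spherical variant is used:
members are unit-normalized, the centroid is their renormalized mean,
and the objective is the summed cosine distance to the centroid — the
consistent minimizer for cosine dissimilarity, chosen because a
squared-Euclidean WCSS stopping rule is not meaningful for an
angle-based metric. Assignment ties break toward the lowest cluster
index; an emptied cluster is re-seeded with the worst-fit point; the
objective is asserted non-increasing at every iteration. k is fixed to 3
in the pipeline (normal / acute / sequela) and configurable in the
library.

Cluster labels are arbitrary, so de-novo clusterings are aligned to the
clinical reference by an optimal one-to-one assignment maximizing
agreement (identical to enumerating label permutations at k ≤ 4) before
accuracy is computed. The packaged reference table's labels are already
matched to the clinical classes, so its metrics are computed *without*
alignment.

## Evaluation and rounding

The weighted F-score weights each reference class's best-matching
cluster F by the class's share of subjects; pairs with empty
intersection contribute zero. F equals 1 exactly when the partitions
coincide (verified exhaustively on 6 subjects). F is reported at
2-decimal precision; accuracies as integer percent with half-up
rounding; binomial CIs use the Wald normal approximation with z = 1.96,
clipped to [0, 100]. These rounding rules are part of the contract: the
package's reference-table metrics are asserted digit-for-digit in the
test suite.

Two documented irregularities of the reference table: the prose
accuracy of 74% for the semiautomatic/Euclidean column is not derivable
from the column itself (which yields 13/19 = 68% under every label
permutation) and is excluded from the asserted values; and the printed
interval 76%–97% for 89% accuracy is not the Wald interval (whose upper
bound clips at 100%), so only the Wald-consistent intervals are
asserted.

## Numerical choices and limitations

* Smoothing: isotropic Gaussian, σ = FWHM/√(8 ln 2) converted per-axis
  to voxel units, reflective boundaries (conserves mean intensity);
  applied before segmentation and fingerprinting. Default FWHM 3 mm.
* Midplane convention: even-width grids split exactly in half; the
  center column of odd-width grids belongs to neither hemisphere.
* The tensor fit is the plain log-linear estimator — no weighting,
  no RESTORE-style robustness; adequate at the phantom's SNR.
* Problem sizes in tests and examples (desk-scale 48×48×20 grids,
  19-subject cohorts, 100 restarts) were chosen so the full suite runs
  in well under a minute; all are configurable.
* Only the largest connected component is returned by the semiautomatic
  segmentation: multi-focal lesions are out of scope.
* `segment_auto_voxelwise` inherits the weaknesses of group statistics
  for single-lesion detection: individual lesions at discordant
  locations dilute each other, which is visible as the automatic
  method's lower F on heterogeneous cohorts.
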