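"""Full synthetic pipeline: simulate a cohort, build fingerprints from
ground-truth lesion ROIs, cluster and evaluate.

Simulates 8 normal / 8 acute / 3 sequela subjects (2% Rician noise),
smooths with a 3 mm FWHM Gaussian, builds each subject's 20-element
target/mirror intensity-ratio fingerprint, and clusters with k-means
(k = 3) under both distance metrics.
"""

from neurofp import make_cohort, PhantomParams
from neurofp.pipeline import (cluster_fingerprints, cohort_fingerprints,
                              evaluate_labels)

cohort = make_cohort(8, 8, 3, PhantomParams(), master_seed=42)
frame = cohort_fingerprints(cohort, roi_method="manual")

for metric in ("euclidean", "cosine"):
    result = cluster_fingerprints(frame, metric, k=3, seed=42, n_restarts=100)
    report = evaluate_labels(frame["class"], result.labels, align=True)
    print(f"{metric:9s}  F = {report['f_score']:.2f}  "
          f"accuracy = {report['accuracy_percent']}% "
          f"(95% CI {report['ci_low_percent']}-{report['ci_high_percent']}%)")

print()
print("With perfectly localized (ground-truth) lesions the acute (ratio > 1)")
print("and sequela (ratio < 1) fingerprints are linearly separable from the")
print("normals (ratio ~ 1), so both metrics recover all 19 class labels.")
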