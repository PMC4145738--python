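"""Score the packaged 19-subject reference table.

Recomputes, for each segmentation method (manual / semiautomatic /
automatic) and distance metric (Euclidean / Cosine), the weighted
clustering F-score and the direct-match accuracy of the published
cluster labels against the clinical diagnosis (1 normal, 2 acute stroke,
3 stroke sequela).
"""

from neurofp import reproduce_table1

report = reproduce_table1()
print(report[["f_score", "accuracy_percent", "ci_low", "ci_high"]])
print()
print("F = 1 for the manual/Euclidean column means that clustering the")
print("manually segmented fingerprints reproduced the clinical classes")
print("exactly; the automatic method's lower F (~0.6) reflects frequent")
print("mislabelling in all three groups.")
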