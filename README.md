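# neurofp

DWI-based neural fingerprinting for ischemic-stroke subtype clustering.

## The problem

Diffusion-weighted MRI (DWI) separates acute ischemic stroke (restricted
diffusion, hyperintense lesions, reduced ADC) from chronic stroke sequela
(elevated diffusivity, hypointense lesions), but simple intensity
thresholding localizes lesions without characterizing their physiology.
`neurofp` implements a *neural fingerprint*: for a subject imaged with one
b=0 volume and 20 diffusion-weighted gradients (b = 1000 s/mm², constant
gradient order across subjects), the fingerprint is the vector

&nbsp;&nbsp;&nbsp;&nbsp;x = (x₁, …, x₂₀),&nbsp;&nbsp;
x_g = mean(S_g | target ROI) / mean(S_g | mirror ROI)

— the ratio of mean DWI intensity in a lesion (target) ROI to that in its
contralateral mirror ROI, per gradient g. The mirror ratio cancels
inter-subject gain, so acute lesions push ratios above 1 and sequela
below 1. Fingerprints are clustered with k-means (k = 3) under Euclidean
distance D_E = ‖x_s − x_t‖ or cosine distance
D_C = 1 − x_s·x_t / (‖x_s‖‖x_t‖), and scored against the clinical classes
P₁…P_s with the class-size-weighted F measure

&nbsp;&nbsp;&nbsp;&nbsp;F = Σ_j (|P_j| / n) · max_i 2·P·R / (P + R),

with precision P = |P_j ∩ C_i| / |C_i| and recall R = |P_j ∩ C_i| / |P_j|.

The package provides three target-ROI strategies (manual masks with rater
intersection; semiautomatic hemispheric difference-map thresholding with
KDE-derived thresholds; a simplified automatic voxelwise FA group
comparison), a synthetic DWI phantom cohort generator with ground-truth
lesions and Rician noise, and the evaluation stack (weighted F, accuracy
with Wald CIs, Bland–Altman interrater statistics). It is aimed at
researchers prototyping contralateral-asymmetry features for stroke
classification, entirely self-contained on synthetic data.

## Worked example

```sh
python examples/02_phantom_pipeline.py
```

simulates 8 normal / 8 acute / 3 sequela subjects (48×48×20 voxels,
2% Rician noise, master seed 42), builds fingerprints from the
ground-truth lesion masks and clusters them:

```
euclidean  F = 1.00  accuracy = 100% (95% CI 100-100%)
cosine     F = 1.00  accuracy = 100% (95% CI 100-100%)
```

With perfectly localized lesions the acute (ratio > 1), sequela
(ratio < 1) and normal (ratio ≈ 1) fingerprints are cleanly separable, so
all 19 class labels are recovered. `examples/03_semiautomatic_segmentation.py`
shows the threshold-learning path (on its small demo cohort it prints
`t1 = -6.7, t2 = 5.9` and segments a held-out acute lesion at Dice 0.64),
and `examples/01_reference_table_metrics.py` scores the packaged
19-subject clinical reference table:

```
        f_score  accuracy_percent  ci_low  ci_high
column
ME         1.00               100     100      100
MC         0.69                68      48       89
SE         0.75                68      48       89
SC         0.89                89      76      100
AE         0.60                58      36       80
AC         0.66                63      41       85
```

(M/S/A = manual, semiautomatic, automatic ROI; E/C = Euclidean, cosine.)

The same pipeline is scriptable from the shell via the `neurofp` command
(`simulate`, `smooth`, `segment`, `fingerprint`, `cluster`, `evaluate`,
`pipeline`, `reproduce-table1`); try `neurofp pipeline --method manual
--metric euclidean --out run1`.

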