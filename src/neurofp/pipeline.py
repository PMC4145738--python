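"""End-to-end orchestration: cohort on disk, ROI selection per method,
fingerprint tables, clustering and evaluation.

Per-method target-ROI conventions
---------------------------------
* ``manual`` — the subject's (rater-drawn or ground-truth) lesion mask;
  normal subjects, who have no lesion, get the left hemisphere as target,
  which yields near-unity fingerprints.
* ``semiauto`` — thresholds learnt from one reference subject per class
  are applied to every subject's hemispheric difference map; a
  ``no-lesion`` outcome falls back to the left hemisphere.
* ``auto`` — a single group-level ROI (voxels with significantly reduced
  patient FA) is used as every subject's target; if the group test finds
  nothing the left hemisphere is used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterResult, align_labels, kmeans
from .errors import ValidationError
from .evaluation import accuracy, clustering_f_score, wald_ci
from .fingerprint import build_fingerprint, fingerprints_to_frame, frame_to_matrix
from .io import RoiMask, read_dwi, read_mask, write_dwi, write_mask
from .phantom import PhantomParams, SyntheticSubject, make_cohort
from .preprocess import gaussian_smooth, mean_over_gradients
from .roi import (
    derive_thresholds,
    fa_map,
    fit_tensor,
    hemisphere_mask,
    pooled_roi_differences,
    segment_auto_voxelwise,
    segment_semiauto,
)

__all__ = [
    "RunConfig",
    "write_cohort",
    "read_cohort",
    "cohort_fingerprints",
    "cluster_fingerprints",
    "evaluate_labels",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of a full run."""

    n_normal: int = 8
    n_acute: int = 8
    n_sequela: int = 3
    master_seed: int = 42
    noise_sigma_frac: float = 0.02
    smoothing_fwhm_mm: float = 3.0
    roi_method: str = "manual"
    metric: str = "euclidean"
    k: int = 3
    cluster_seed: int = 0
    n_restarts: int = 100
    alpha: float = 0.005
    out_dir: str = "neurofp_run"

    def to_file(self, path) -> Path:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValidationError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            kwargs[key] = type(current)(raw)
        return cls(**kwargs)


def write_cohort(subjects: list[SyntheticSubject], out_dir) -> Path:
    """Write per-subject NIfTI + bval/bvec + truth/brain masks and a
    cohort manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        stem = out / f"sub-{s.subject_id:02d}"
        write_dwi(s.dwi, f"{stem}_dwi.nii.gz", f"{stem}.bval", f"{stem}.bvec")
        write_mask(s.brain_mask, f"{stem}_brain.nii.gz", s.dwi.voxel_size)
        write_mask(s.truth_lesion, f"{stem}_lesion.nii.gz", s.dwi.voxel_size)
        rows.append({"subject": s.subject_id, "class": s.clinical_class,
                     "seed": s.seed, "n_lesion_voxels": s.truth_lesion.n_voxels})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def read_cohort(cohort_dir) -> list[SyntheticSubject]:
    """Re-read a cohort written by :func:`write_cohort`."""
    cohort = Path(cohort_dir)
    manifest = pd.read_csv(cohort / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        stem = cohort / f"sub-{int(row['subject']):02d}"
        dwi = read_dwi(f"{stem}_dwi.nii.gz", f"{stem}.bval", f"{stem}.bvec")
        brain = read_mask(f"{stem}_brain.nii.gz", dwi.spatial_shape)
        lesion = read_mask(f"{stem}_lesion.nii.gz", dwi.spatial_shape)
        subjects.append(SyntheticSubject(
            subject_id=int(row["subject"]), clinical_class=int(row["class"]),
            dwi=dwi, truth_lesion=lesion, brain_mask=brain, seed=int(row["seed"]),
        ))
    return subjects


def _default_target(subject: SyntheticSubject) -> RoiMask:
    """Target ROI when no lesion is available: the left hemisphere."""
    return hemisphere_mask(subject.brain_mask, "left")


def _manual_targets(subjects) -> list[RoiMask]:
    return [s.truth_lesion if not s.truth_lesion.is_empty else _default_target(s)
            for s in subjects]


def _semiauto_targets(subjects, smoothed, mean_images) -> list[RoiMask]:
    # one reference subject per class (first of each), mirroring the
    # small arbitrary training set the method is designed around
    refs: dict[int, int] = {}
    for i, s in enumerate(subjects):
        refs.setdefault(s.clinical_class, i)
    if set(refs) != {1, 2, 3}:
        raise ValidationError("semiauto thresholds need one reference subject "
                              "per class (normal, acute, sequela)")
    pooled = {}
    for cls, i in refs.items():
        s = subjects[i]
        target = s.truth_lesion if not s.truth_lesion.is_empty else _default_target(s)
        pooled[cls] = pooled_roi_differences(mean_images[i], s.brain_mask, target)
    thresholds = derive_thresholds(pooled[1], pooled[2], pooled[3])
    targets = []
    for i, s in enumerate(subjects):
        roi, kind = segment_semiauto(mean_images[i], s.brain_mask, thresholds)
        targets.append(roi if kind != "no-lesion" else _default_target(s))
    return targets


def _auto_targets(subjects, smoothed, alpha: float) -> list[RoiMask]:
    fa_maps = [fa_map(fit_tensor(img, s.brain_mask))
               for img, s in zip(smoothed, subjects)]
    patients = [fa for fa, s in zip(fa_maps, subjects) if s.clinical_class != 1]
    controls = [fa for fa, s in zip(fa_maps, subjects) if s.clinical_class == 1]
    group_roi = segment_auto_voxelwise(patients, controls, alpha=alpha)
    return [
        RoiMask(group_roi.data & s.brain_mask.data)
        if (group_roi.data & s.brain_mask.data).any()
        else _default_target(s)
        for s in subjects
    ]


def cohort_fingerprints(
    subjects: list[SyntheticSubject],
    roi_method: str = "manual",
    smoothing_fwhm_mm: float = 3.0,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Smooth, segment with the chosen method, and build the cohort's
    fingerprint table."""
    smoothed = [gaussian_smooth(s.dwi, smoothing_fwhm_mm) for s in subjects]
    mean_images = [mean_over_gradients(img) for img in smoothed]
    if roi_method == "manual":
        targets = _manual_targets(subjects)
    elif roi_method == "semiauto":
        targets = _semiauto_targets(subjects, smoothed, mean_images)
    elif roi_method == "auto":
        targets = _auto_targets(subjects, smoothed, alpha)
    else:
        raise ValidationError(f"unknown roi_method {roi_method!r}")
    fps = [
        build_fingerprint(img, tgt, subject_id=s.subject_id, roi_method=roi_method)
        for img, tgt, s in zip(smoothed, targets, subjects)
    ]
    return fingerprints_to_frame(fps, [s.clinical_class for s in subjects])


def cluster_fingerprints(
    frame: pd.DataFrame,
    metric: str = "euclidean",
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 100,
) -> ClusterResult:
    x, _ = frame_to_matrix(frame)
    return kmeans(x, k, metric=metric, seed=seed, n_restarts=n_restarts)


def evaluate_labels(reference, labels, align: bool = True) -> dict:
    ref = np.asarray(reference, int)
    lab = np.asarray(labels, int)
    if align:
        lab = align_labels(lab, ref)
    frac, pct = accuracy(ref, lab, align=False)
    matches = int((ref == lab).sum())
    lo, hi = wald_ci(matches, ref.size)
    return {
        "f_score": clustering_f_score(ref, lab),
        "accuracy_fraction": frac,
        "accuracy_percent": pct,
        "ci_low_percent": lo,
        "ci_high_percent": hi,
        "n": int(ref.size),
        "aligned_labels": lab.tolist(),
    }


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Simulate (or reuse) a cohort and run smooth → segment →
    fingerprint → cluster → align → evaluate, writing all intermediates
    and a provenance record under ``config.out_dir``."""
    params = PhantomParams(noise_sigma_frac=config.noise_sigma_frac)
    subjects = make_cohort(config.n_normal, config.n_acute, config.n_sequela,
                           params, config.master_seed)
    frame = cohort_fingerprints(subjects, config.roi_method,
                                config.smoothing_fwhm_mm, config.alpha)
    result = cluster_fingerprints(frame, config.metric, config.k,
                                  config.cluster_seed, config.n_restarts)
    classes = frame["class"].to_numpy(int)
    report = evaluate_labels(classes, result.labels, align=True)
    report.update(metric=config.metric, roi_method=config.roi_method,
                  objective=result.objective, n_iter=result.n_iter,
                  raw_labels=result.labels.tolist(),
                  reference=classes.tolist())
    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "fingerprints.csv", index=False)
        pd.DataFrame({
            "subject": frame["subject"], "class": classes,
            "raw_label": result.labels,
            "aligned_label": report["aligned_labels"],
        }).to_csv(out / "labels.csv", index=False)
        config.to_file(out / "config.txt")
        prov = {"version": __version__, **{k: v for k, v in report.items()
                                           if not isinstance(v, list)}}
        (out / "report.json").write_text(json.dumps(prov, indent=2) + "\n")
    return report
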