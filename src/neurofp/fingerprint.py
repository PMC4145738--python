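"""Neural fingerprint construction.

A subject's fingerprint is a vector of 20 positive ratios, one per
diffusion-weighted gradient: the mean intensity inside the target ROI
divided by the mean intensity inside the contralateral mirror ROI.  The
mirror ratio cancels inter-subject gain (multiplying the whole image by
any c > 0 leaves the fingerprint unchanged), so acute lesions (restricted
diffusion, hyperintense DWI) push ratios above 1 and chronic sequela
(elevated diffusivity, hypointense) push them below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateRoiError, ValidationError
from .io import DwiImage, RoiMask
from .roi import mirror_mask

__all__ = ["Fingerprint", "build_fingerprint", "fingerprints_to_frame",
           "frame_to_matrix"]

ROI_METHODS = ("manual", "semiauto", "auto")


@dataclass(frozen=True)
class Fingerprint:
    """Ordered vector of target/mirror mean-intensity ratios, one element
    per b>0 gradient of the cohort's (constant-order) scheme."""

    values: np.ndarray
    subject_id: int
    roi_method: str = "manual"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValidationError("fingerprint values must be finite and > 0")
        object.__setattr__(self, "values", v)
        if self.roi_method not in ROI_METHODS:
            raise ValidationError(f"roi_method must be one of {ROI_METHODS}")

    def __len__(self) -> int:
        return int(self.values.size)


def build_fingerprint(
    image: DwiImage,
    target: RoiMask,
    mirror: RoiMask | None = None,
    subject_id: int = 0,
    roi_method: str = "manual",
) -> Fingerprint:
    """Ratio of target-ROI to mirror-ROI mean intensity for each b>0
    volume; the b=0 volume is excluded.

    The mirror defaults to the target reflected across the midsagittal
    plane; passing one explicitly overrides that."""
    if target.is_empty:
        raise ValidationError("target ROI is empty")
    target.check_grid(image.spatial_shape)
    if mirror is None:
        mirror = mirror_mask(target)
    mirror.check_grid(image.spatial_shape)
    if mirror.is_empty:
        raise ValidationError("mirror ROI is empty")

    idx = image.scheme.dwi_indices
    tgt_means = image.data[target.data][:, idx].mean(axis=0)
    mir_means = image.data[mirror.data][:, idx].mean(axis=0)
    if np.any(mir_means == 0):
        raise DegenerateRoiError("mirror ROI has zero mean signal at some gradient")
    return Fingerprint(tgt_means / mir_means, subject_id, roi_method)


def fingerprints_to_frame(
    fingerprints: list[Fingerprint], classes: list[int]
) -> pd.DataFrame:
    """Cohort fingerprint table: subject, class, g01..gNN, roi_method."""
    if len(fingerprints) != len(classes):
        raise ValidationError("one class label per fingerprint required")
    n = len(fingerprints[0])
    cols = [f"g{i + 1:02d}" for i in range(n)]
    rows = []
    for fp, cls in zip(fingerprints, classes):
        if len(fp) != n:
            raise ValidationError("fingerprints of unequal length")
        rows.append({"subject": fp.subject_id, "class": cls,
                     **dict(zip(cols, fp.values)), "roi_method": fp.roi_method})
    return pd.DataFrame(rows)


def frame_to_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(n_subjects, n_gradients) feature matrix and class vector from a
    fingerprint table."""
    cols = [c for c in frame.columns if c.startswith("g") and c[1:].isdigit()]
    return frame[cols].to_numpy(float), frame["class"].to_numpy(int)
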