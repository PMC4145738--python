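"""Target/mirror ROI production by three strategies.

* **manual** — rater-drawn masks, combined by intersection; the mirror
  ROI is the target reflected across the midsagittal plane.
* **semiautomatic** — hemispheric difference-map histogram thresholding:
  two intensity-difference thresholds, learnt from one reference subject
  per class, separate hypointense (sequela-like) and hyperintense
  (acute-like) voxels from normal tissue.
* **automatic** — a voxelwise group comparison of fractional-anisotropy
  maps between patients and controls (one-sided Welch t-test, uncorrected
  P < 0.005 by default).  This is a deliberately simplified, self-contained
  alternative to skeleton-based group statistics: no FA skeletonization or
  projection is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateRoiError, ValidationError
from .io import DwiImage, RoiMask
from .phantom import TensorField

__all__ = [
    "ThresholdPair",
    "mirror_mask",
    "mirror_image",
    "intersect_rater_masks",
    "hemisphere_mask",
    "difference_map",
    "derive_thresholds",
    "segment_semiauto",
    "fit_tensor",
    "fa_map",
    "segment_auto_voxelwise",
]

#: 26-connectivity structuring element for 3D connected components.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdPair:
    """Lower (sequela vs normal) and upper (normal vs acute) intensity-
    difference thresholds for semiautomatic lesion identification."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t1) and np.isfinite(self.t2)):
            raise ValidationError("thresholds must be finite")
        if not self.t1 < self.t2:
            raise ValidationError(f"need t1 < t2, got t1={self.t1}, t2={self.t2}")


def mirror_mask(mask: RoiMask) -> RoiMask:
    """Reflect a mask across the grid midplane of axis 0:
    voxel (x, y, z) -> (Nx-1-x, y, z)."""
    return RoiMask(mask.data[::-1, :, :].copy())


def mirror_image(volume: np.ndarray) -> np.ndarray:
    """Reflect a 3D image across the axis-0 midplane."""
    return volume[::-1, :, :]


def intersect_rater_masks(mask_a: RoiMask, mask_b: RoiMask) -> RoiMask:
    """Voxelwise AND of two raters' target masks; an empty intersection
    signals rater disagreement and is an error."""
    if mask_a.data.shape != mask_b.data.shape:
        raise ValidationError("rater masks on different grids")
    inter = mask_a.data & mask_b.data
    if not inter.any():
        raise DegenerateRoiError("rater masks do not intersect")
    return RoiMask(inter)


def hemisphere_mask(brain_mask: RoiMask, side: str) -> RoiMask:
    """Brain voxels strictly within one hemisphere (the midplane column
    of an odd-width grid belongs to neither)."""
    nx = brain_mask.data.shape[0]
    x = np.arange(nx)
    if side == "left":
        keep = x < nx / 2.0 - (nx % 2) * 0.5
    elif side == "right":
        keep = x > nx / 2.0 - 0.5 + (nx % 2) * 0.5
    else:
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    out = brain_mask.data & keep[:, None, None]
    if not out.any():
        raise ValidationError(f"no brain voxels in {side} hemisphere")
    return RoiMask(out)


def difference_map(mean_image: np.ndarray, brain_mask: RoiMask) -> np.ndarray:
    """Per brain voxel v: intensity(v) - intensity(mirror(v)); zero
    outside the brain.  Antisymmetric by construction."""
    diff = mean_image - mirror_image(mean_image)
    diff[~brain_mask.data] = 0.0
    return diff


def _density_crossing(
    sample_lo: np.ndarray, sample_hi: np.ndarray
) -> tuple[float, bool]:
    """Crossing point of two Gaussian-KDE densities (Silverman bandwidth),
    searched between the two sample means.

    Returns (threshold, crossed).  With no sign change between the means
    — e.g. identical distributions — falls back to the midpoint of the
    means and reports ``crossed=False``.
    """
    m_lo, m_hi = float(np.mean(sample_lo)), float(np.mean(sample_hi))
    if m_lo > m_hi:
        m_lo, m_hi = m_hi, m_lo
        sample_lo, sample_hi = sample_hi, sample_lo
    try:
        kde_lo = stats.gaussian_kde(sample_lo, bw_method="silverman")
        kde_hi = stats.gaussian_kde(sample_hi, bw_method="silverman")
    except (np.linalg.LinAlgError, ValueError):
        return 0.5 * (m_lo + m_hi), False
    if m_hi - m_lo <= 0:
        return m_lo, False
    grid = np.linspace(m_lo, m_hi, 512)
    delta = kde_lo(grid) - kde_hi(grid)
    sign_change = np.flatnonzero(np.diff(np.sign(delta)) != 0)
    if sign_change.size == 0:
        return 0.5 * (m_lo + m_hi), False
    # crossing nearest the midpoint of the two class means
    mid = 0.5 * (m_lo + m_hi)
    i = sign_change[np.argmin(np.abs(grid[sign_change] - mid))]
    # linear interpolation of the zero of delta between grid[i], grid[i+1]
    x0, x1, d0, d1 = grid[i], grid[i + 1], delta[i], delta[i + 1]
    t = x0 if d1 == d0 else x0 - d0 * (x1 - x0) / (d1 - d0)
    return float(t), True


def derive_thresholds(
    normal_diffs: np.ndarray,
    acute_diffs: np.ndarray,
    sequela_diffs: np.ndarray,
) -> ThresholdPair:
    """Learn the two lesion-identification thresholds from the pooled
    difference-map values inside one reference subject's target ROI per
    class.

    Each class's values form an empirical distribution; densities are
    estimated by Gaussian KDE with Silverman's bandwidth.  ``t1`` is the
    density crossing between the sequela (hypointense, negative
    differences) and normal distributions, ``t2`` the crossing between
    normal and acute (hyperintense).  A missing crossing falls back to
    the midpoint of the class means with a warning.
    """
    for name, s in (("normal", normal_diffs), ("acute", acute_diffs),
                    ("sequela", sequela_diffs)):
        if np.asarray(s).size < 2:
            raise ValidationError(f"reference class {name!r} has < 2 samples")
    t1, ok1 = _density_crossing(np.asarray(sequela_diffs, float).ravel(),
                                np.asarray(normal_diffs, float).ravel())
    t2, ok2 = _density_crossing(np.asarray(normal_diffs, float).ravel(),
                                np.asarray(acute_diffs, float).ravel())
    if not (ok1 and ok2):
        warnings.warn(
            "no density crossing between reference classes; "
            "falling back to midpoint of class means",
            stacklevel=2,
        )
    if not t1 < t2:
        # degenerate references (e.g. identical distributions): order by
        # a tiny separation around their midpoint to keep the invariant
        mid = 0.5 * (t1 + t2)
        eps = max(1e-9, 1e-6 * (abs(mid) + 1.0))
        t1, t2 = mid - eps, mid + eps
        warnings.warn("degenerate threshold crossing; thresholds collapsed "
                      "to an epsilon interval", stacklevel=2)
    return ThresholdPair(t1, t2)


def pooled_roi_differences(
    mean_image: np.ndarray, brain_mask: RoiMask, target: RoiMask
) -> np.ndarray:
    """Difference-map values within a reference target ROI."""
    diff = difference_map(mean_image, brain_mask)
    return diff[target.data & brain_mask.data]


def segment_semiauto(
    mean_image: np.ndarray,
    brain_mask: RoiMask,
    thresholds: ThresholdPair,
) -> tuple[RoiMask, str]:
    """Threshold the hemispheric difference map into a lesion ROI.

    Candidate sets are {diff > t2} (acute-like) and {diff < t1}
    (sequela-like) within the brain; the set with the larger summed
    absolute difference wins, and the returned ROI is its largest
    26-connected component (ties broken by larger summed |diff|).  An
    empty result is the flagged outcome ``"no-lesion"``, not an error.
    """
    diff = difference_map(mean_image, brain_mask)
    acute_cand = (diff > thresholds.t2) & brain_mask.data
    seq_cand = (diff < thresholds.t1) & brain_mask.data
    w_acute = float(np.abs(diff[acute_cand]).sum())
    w_seq = float(np.abs(diff[seq_cand]).sum())
    empty = RoiMask(np.zeros_like(brain_mask.data))
    if w_acute == 0.0 and w_seq == 0.0:
        return empty, "no-lesion"
    if w_acute >= w_seq:
        cand, kind = acute_cand, "acute"
    else:
        cand, kind = seq_cand, "sequela"
    labels, n = ndimage.label(cand, structure=_CONN26)
    if n == 0:
        return empty, "no-lesion"
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    tied = np.flatnonzero(sizes == best_size) + 1
    if tied.size > 1:
        weights = ndimage.sum_labels(np.abs(diff), labels, index=tied)
        best = tied[int(np.argmax(weights))]
    else:
        best = int(tied[0])
    return RoiMask(labels == best), kind


def fit_tensor(image: DwiImage, brain_mask: RoiMask) -> TensorField:
    """Per-voxel log-linear least-squares diffusion-tensor fit.

    Solves ln(S_i / S0) = -b_i g_i' D g_i over the b>0 volumes; S0 is the
    mean of the b=0 volumes.  Voxels with any non-positive signal are
    skipped (left zero).  Negative eigenvalues of the fitted tensor are
    clipped to zero to keep the field positive semidefinite.
    """
    scheme = image.scheme
    dwi_idx = scheme.dwi_indices
    b0_idx = scheme.b0_indices
    if dwi_idx.size < 6:
        raise ValidationError(
            f"tensor fit needs >= 6 diffusion directions, got {dwi_idx.size}"
        )
    if b0_idx.size < 1:
        raise ValidationError("tensor fit needs at least one b=0 volume")
    brain_mask.check_grid(image.spatial_shape)

    g = scheme.bvecs[dwi_idx]
    b = scheme.bvals[dwi_idx]
    # design rows: b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)
    design = b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    pinv = np.linalg.pinv(design)  # (6, n_dir)

    mask = brain_mask.data
    s = image.data[mask][:, dwi_idx]       # (n_vox, n_dir)
    s0 = image.data[mask][:, b0_idx].mean(axis=1)
    ok = (s > 0).all(axis=1) & (s0 > 0)
    comps_flat = np.zeros((mask.sum(), 6))
    if ok.any():
        y = -np.log(s[ok] / s0[ok, None])   # (n_ok, n_dir)
        comps_flat[ok] = y @ pinv.T

    comps = np.zeros((*image.spatial_shape, 6))
    comps[mask] = comps_flat
    field = TensorField(comps, image.voxel_size)

    # clip negative eigenvalues to keep tensors positive semidefinite
    fitted = mask.copy()
    fitted[mask] = ok
    m = field.as_matrices()[fitted]
    w, v = np.linalg.eigh(m)
    if (w < 0).any():
        w = np.clip(w, 0.0, None)
        m = np.einsum("...ij,...j,...kj->...ik", v, w, v)
        comps_clipped = np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
             m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)
        comps[fitted] = comps_clipped
        field = TensorField(comps, image.voxel_size)
    return field


def fa_map(field: TensorField) -> np.ndarray:
    """Fractional anisotropy of each voxel's tensor.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, and 0 where
    all eigenvalues vanish.  Values are clipped to [0, 1].
    """
    shape = field.spatial_shape
    nonzero = np.any(field.components != 0, axis=-1)
    fa = np.zeros(shape)
    if nonzero.any():
        w = np.linalg.eigvalsh(field.as_matrices()[nonzero])
        mean_w = w.mean(axis=1, keepdims=True)
        num = np.sqrt(((w - mean_w) ** 2).sum(axis=1))
        den = np.sqrt((w**2).sum(axis=1))
        vals = np.zeros(len(w))
        pos = den > 0
        vals[pos] = np.sqrt(1.5) * num[pos] / den[pos]
        fa[nonzero] = np.clip(vals, 0.0, 1.0)
    return fa


def segment_auto_voxelwise(
    patient_fa: list[np.ndarray],
    control_fa: list[np.ndarray],
    alpha: float = 0.005,
) -> RoiMask:
    """Voxelwise FA group comparison: the target ROI is the set of voxels
    where patients' FA is significantly *lower* than controls' (one-sided
    Welch t-test, uncorrected P < ``alpha``).

    Voxels with zero variance in both groups (e.g. background) are
    excluded from testing.
    """
    if len(patient_fa) < 2 or len(control_fa) < 2:
        raise ValidationError("need >= 2 FA images per group")
    pat = np.stack(patient_fa)
    ctl = np.stack(control_fa)
    if pat.shape[1:] != ctl.shape[1:]:
        raise ValidationError("FA images on different grids")
    testable = (pat.var(axis=0) > 0) | (ctl.var(axis=0) > 0)
    roi = np.zeros(pat.shape[1:], dtype=bool)
    if not testable.any():
        return RoiMask(roi)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            pat[:, testable], ctl[:, testable],
            equal_var=False, alternative="less", axis=0,
        )
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    roi[testable] = p < alpha
    return RoiMask(roi)
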