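"""Imaging I/O: DWI volumes with FSL-style gradient tables, binary ROI
masks, and the packaged 19-subject clustering reference table.

Conventions
-----------
Voxel indices are 0-based.  Axis 0 of every grid is the left-right axis and
the midsagittal plane is the grid midplane of that axis; inputs are assumed
co-registered to a symmetric template space.  Gradient tables use the FSL
dialect: one whitespace-separated row of b-values in ``.bval`` and three
rows (x, y, z components) of direction cosines in ``.bvec``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "GradientScheme",
    "DwiImage",
    "RoiMask",
    "default_scheme",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "load_table1_fixture",
    "TABLE1_METHOD_COLUMNS",
]

#: Fixed seed used once to draw the package's default set of 20 gradient
#: directions.  The directions are pseudo-random but *constant*: every
#: subject of a cohort shares the same ordering, which is all the
#: fingerprint construction requires.
DEFAULT_SCHEME_SEED = 1105

#: Table 1 method columns: (segmentation method) x (distance metric).
TABLE1_METHOD_COLUMNS = ("ME", "MC", "SE", "SC", "AE", "AC")

_DIRECTION_NORM_TOL = 1e-3


@dataclass(frozen=True)
class GradientScheme:
    """b-values (s/mm^2) and unit direction vectors of an acquisition.

    The default clinical-style scheme has exactly one b=0 volume followed
    by 20 b=1000 directions.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    order_tag: str = "unnamed"

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValidationError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValidationError("negative b-value in gradient scheme")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _DIRECTION_NORM_TOL):
            bad = norms[np.abs(norms - 1.0) > _DIRECTION_NORM_TOL]
            raise ValidationError(
                f"diffusion direction norm(s) {bad} deviate from unit length "
                f"by more than {_DIRECTION_NORM_TOL}"
            )
        # re-normalize directions that are within tolerance of unit length
        fixed = bvecs.copy()
        fixed[dw] = bvecs[dw] / norms[:, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", fixed)

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals == 0)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals > 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GradientScheme):
            return NotImplemented
        return (
            np.array_equal(self.bvals, other.bvals)
            and np.allclose(self.bvecs, other.bvecs, atol=1e-12)
        )


def default_scheme(n_directions: int = 20, b: float = 1000.0) -> GradientScheme:
    """The package's default acquisition: 1 b=0 volume + ``n_directions``
    pseudo-random unit directions at ``b`` s/mm^2, in a fixed order."""
    rng = np.random.default_rng(DEFAULT_SCHEME_SEED)
    v = rng.normal(size=(n_directions, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros(3), v])
    return GradientScheme(bvals, bvecs, order_tag=f"default-{n_directions}dir")


@dataclass
class DwiImage:
    """A 4D DWI intensity grid (x, y, z, volume) bound to its scheme.

    Axis 0 is left-right; intensities are finite and non-negative.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    scheme: GradientScheme

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValidationError(f"DWI data must be 4D, got {data.ndim}D")
        if data.size == 0:
            raise ValidationError("empty DWI image")
        if data.shape[3] != len(self.scheme):
            raise FormatError(
                f"image has {data.shape[3]} volumes but gradient scheme has "
                f"{len(self.scheme)} entries"
            )
        if not np.all(np.isfinite(data)):
            raise ValidationError("non-finite intensity in DWI image")
        if np.any(data < 0):
            raise ValidationError("negative intensity in DWI image")
        self.data = data
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volume(self, i: int) -> np.ndarray:
        return self.data[..., i]


@dataclass
class RoiMask:
    """Binary 3D mask on a DWI voxel grid (target or mirror ROI)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError(f"mask must be 3D, got {data.ndim}D")
        self.data = data != 0

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def check_grid(self, shape: tuple[int, int, int]) -> "RoiMask":
        if self.data.shape != tuple(shape):
            raise ValidationError(
                f"mask grid {self.data.shape} does not match image grid {tuple(shape)}"
            )
        return self


def _affine(voxel_size: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_dwi(image_path, bval_path, bvec_path) -> DwiImage:
    """Read a 4D NIfTI plus FSL-style .bval/.bvec into a validated DwiImage.

    Raises FormatError when the gradient-table entry count disagrees with
    the image's 4th dimension, ValidationError for non-unit directions.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: 3 rows of N columns
    if bvals.size != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise FormatError(
            f"gradient table has {bvals.size} b-values / {bvecs.shape[0]} "
            f"directions but image has {data.shape[3]} volumes"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    scheme = GradientScheme(bvals, bvecs, order_tag=Path(str(bval_path)).stem)
    return DwiImage(data, voxel_size, scheme)


def write_dwi(image: DwiImage, image_path, bval_path, bvec_path) -> tuple[Path, Path, Path]:
    """Write a DwiImage as NIfTI + one-line .bval and 3-row .bvec files."""
    nii = nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size))
    nii.header.set_zooms((*image.voxel_size, 1.0))
    nib.save(nii, str(image_path))
    np.savetxt(bval_path, image.scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, image.scheme.bvecs.T, fmt="%.10f")
    return Path(str(image_path)), Path(str(bval_path)), Path(str(bvec_path))


def read_mask(path, expected_shape) -> RoiMask:
    """Read a NIfTI mask, binarizing nonzero voxels, and check its grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return RoiMask(data).check_grid(tuple(expected_shape))


def write_mask(mask: RoiMask, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    nii = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(np.asarray(voxel_size, float)))
    nib.save(nii, str(path))
    return Path(str(path))


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 19-subject clustering reference table.

    Columns: ``subject`` (1-19), ``clinical`` (1 normal, 2 acute stroke,
    3 stroke sequela) and six clustering-label columns, one per
    segmentation method x distance metric: ``ME``/``MC`` (manual ROI,
    Euclidean/Cosine), ``SE``/``SC`` (semiautomatic), ``AE``/``AC``
    (automatic).  All labels are in {1, 2, 3}.
    """
    ref = importlib.resources.files("neurofp.data").joinpath("table1.csv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    expected_cols = ["subject", "clinical", *TABLE1_METHOD_COLUMNS]
    if list(df.columns) != expected_cols:
        raise FormatError(f"fixture columns {list(df.columns)} != {expected_cols}")
    if len(df) != 19:
        raise FormatError(f"fixture has {len(df)} rows, expected 19")
    counts = df["clinical"].value_counts()
    if not (counts.get(1) == 8 and counts.get(2) == 8 and counts.get(3) == 3):
        raise FormatError("fixture clinical class counts are not 8/8/3")
    if not df[expected_cols[1:]].isin([1, 2, 3]).all().all():
        raise FormatError("fixture labels outside {1,2,3}")
    df.attrs["source"] = "packaged transcription"
    return df
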