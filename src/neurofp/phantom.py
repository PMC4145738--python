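"""Synthetic DWI phantoms: left-right symmetric brains with inserted
stroke lesions, diffusion-tensor signal simulation and Rician noise.

The phantom emulates the study conditions every downstream stage is built
for: a cohort of normal controls, acute-stroke subjects (reduced apparent
diffusion coefficient, hence hyperintense DWI lesions) and stroke-sequela
subjects (raised ADC, hypointense lesions), imaged with 1 b=0 volume and
20 diffusion-weighted directions at b = 1000 s/mm^2.

The brain is an axis-0-symmetric ellipsoid of homogeneous, mildly
anisotropic tissue; outside lesions the tensor field equals its own
mirror image about the midsagittal plane, so every contralateral ratio is
exactly 1 in the noiseless case.  Lesions are spheres confined to one
hemisphere that rescale mean diffusivity (``adc_scale``) and fractional
anisotropy (``fa_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import DwiImage, GradientScheme, RoiMask, default_scheme

__all__ = [
    "TensorField",
    "LesionSpec",
    "SyntheticSubject",
    "PhantomParams",
    "make_tensor_field",
    "simulate_signal",
    "add_rician_noise",
    "make_cohort",
]

# Default desk-scale geometry: 48x48x20 voxels at 1x1x5 mm, echoing a
# clinical 1 mm in-plane resolution with 5 mm slices.
DEFAULT_GRID = (48, 48, 20)
DEFAULT_VOXEL_SIZE = (1.0, 1.0, 5.0)

# Healthy-tissue defaults: mean diffusivity 0.8e-3 mm^2/s with mild
# anisotropy; acute lesions reduce ADC, sequela lesions raise it.
DEFAULT_MD = 0.8e-3
DEFAULT_FA = 0.30
ACUTE_ADC_SCALE = 0.6
SEQUELA_ADC_SCALE = 1.8
DEFAULT_LESION_FA_SCALE = 0.7


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors in mm^2/s.

    Stored as 6 components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in the last
    axis; background (non-brain) tensors are zero.
    """

    components: np.ndarray  # (X, Y, Z, 6)
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float)
        if c.ndim != 4 or c.shape[3] != 6:
            raise ValidationError("tensor field must have shape (X, Y, Z, 6)")
        self.components = c
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full (X, Y, Z, 3, 3) symmetric matrices."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.components, -1, 0)
        m = np.empty((*self.spatial_shape, 3, 3))
        m[..., 0, 0] = xx
        m[..., 1, 1] = yy
        m[..., 2, 2] = zz
        m[..., 0, 1] = m[..., 1, 0] = xy
        m[..., 0, 2] = m[..., 2, 0] = xz
        m[..., 1, 2] = m[..., 2, 1] = yz
        return m

    def mean_diffusivity(self) -> np.ndarray:
        return self.components[..., :3].mean(axis=-1)


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: voxel-space center, radius in mm, and the
    multiplicative changes it applies to mean diffusivity and anisotropy."""

    center: tuple[int, int, int]
    radius_mm: float
    kind: str  # "acute" | "sequela"
    adc_scale: float | None = None
    fa_scale: float = DEFAULT_LESION_FA_SCALE

    def __post_init__(self) -> None:
        if self.kind not in ("acute", "sequela"):
            raise ValidationError(f"unknown lesion kind {self.kind!r}")
        if self.radius_mm <= 0:
            raise ValidationError("lesion radius must be positive")
        if self.adc_scale is None:
            object.__setattr__(
                self,
                "adc_scale",
                ACUTE_ADC_SCALE if self.kind == "acute" else SEQUELA_ADC_SCALE,
            )
        if self.kind == "acute" and self.adc_scale >= 1:
            raise ValidationError("acute lesions must reduce ADC (adc_scale < 1)")
        if self.kind == "sequela" and self.adc_scale <= 1:
            raise ValidationError("sequela lesions must raise ADC (adc_scale > 1)")


@dataclass
class SyntheticSubject:
    """One simulated subject with its ground truth."""

    subject_id: int
    clinical_class: int  # 1 normal, 2 acute, 3 sequela
    dwi: DwiImage
    truth_lesion: RoiMask
    brain_mask: RoiMask
    seed: int
    tensor_field: TensorField | None = None


@dataclass(frozen=True)
class PhantomParams:
    """Cohort-level generation parameters (the study conditions)."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    base_md: float = DEFAULT_MD
    base_fa: float = DEFAULT_FA
    s0: float = 1000.0
    noise_sigma_frac: float = 0.02  # Rician sigma as a fraction of s0
    lesion_radius_mm: float = 6.0
    acute_adc_scale: float = ACUTE_ADC_SCALE
    sequela_adc_scale: float = SEQUELA_ADC_SCALE
    lesion_fa_scale: float = DEFAULT_LESION_FA_SCALE
    n_directions: int = 20
    b_value: float = 1000.0

    def scheme(self) -> GradientScheme:
        return default_scheme(self.n_directions, self.b_value)


def _prolate_eigenvalues(md: np.ndarray, fa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (l1, l2=l3) of a prolate tensor with the given mean
    diffusivity and fractional anisotropy.

    With l1 = md(1+2d), l2 = l3 = md(1-d) one gets FA^2 = 3d^2/(1+2d^2),
    hence d = FA / sqrt(3 - 2 FA^2).
    """
    fa = np.asarray(fa, dtype=float)
    if np.any((fa < 0) | (fa >= 1)):
        raise ValidationError("base FA must lie in [0, 1)")
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    l1 = md * (1.0 + 2.0 * d)
    l23 = md * (1.0 - d)
    return l1, l23


def _ellipsoid_brain(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-0 symmetric ellipsoidal brain mask filling ~80% of each axis."""
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = 0.4 * nx, 0.4 * ny, 0.4 * nz
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _lesion_sphere(
    grid_shape: tuple[int, int, int],
    voxel_size: np.ndarray,
    center: tuple[int, int, int],
    radius_mm: float,
) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    dx = (x - center[0]) * voxel_size[0]
    dy = (y - center[1]) * voxel_size[1]
    dz = (z - center[2]) * voxel_size[2]
    return dx**2 + dy**2 + dz**2 <= radius_mm**2


def make_tensor_field(
    grid_shape: tuple[int, int, int],
    voxel_size,
    base_md: float,
    base_fa: float,
    lesions: list[LesionSpec] | None = None,
    seed: int | None = None,
) -> tuple[TensorField, RoiMask, RoiMask]:
    """Build the symmetric brain tensor field with lesions applied.

    Returns ``(field, brain_mask, truth_lesion)``.  The principal axis of
    the healthy tensor is the z (inferior-superior) axis, so the field is
    exactly invariant under the axis-0 mirror reflection; a lesion
    crossing the midplane would corrupt its own contralateral reference
    and is rejected.
    """
    if any(s < m for s, m in zip(grid_shape, (16, 16, 8))):
        raise ValidationError(f"grid {grid_shape} below minimum (16, 16, 8)")
    voxel_size = np.asarray(voxel_size, dtype=float).reshape(3)
    lesions = list(lesions or [])
    brain = _ellipsoid_brain(grid_shape)
    nx = grid_shape[0]

    md = np.where(brain, base_md, 0.0)
    fa = np.where(brain, base_fa, 0.0)
    truth = np.zeros(grid_shape, dtype=bool)
    for les in lesions:
        sphere = _lesion_sphere(grid_shape, voxel_size, les.center, les.radius_mm) & brain
        if not sphere.any():
            raise ValidationError(f"lesion at {les.center} lies outside the brain")
        xs = np.flatnonzero(sphere.any(axis=(1, 2)))
        left = xs < nx / 2.0
        if left.any() and (~left).any():
            raise ValidationError(
                f"lesion at {les.center} crosses the midsagittal plane"
            )
        if (truth & sphere).any():
            raise ValidationError("overlapping lesions")
        md[sphere] *= les.adc_scale
        fa[sphere] *= les.fa_scale
        truth |= sphere

    l1, l23 = _prolate_eigenvalues(md, fa)
    comps = np.zeros((*grid_shape, 6))
    comps[..., 0] = l23  # Dxx
    comps[..., 1] = l23  # Dyy
    comps[..., 2] = l1   # Dzz (principal axis inferior-superior)
    field = TensorField(comps, voxel_size)
    return field, RoiMask(brain), RoiMask(truth)


def simulate_signal(field: TensorField, s0: float, scheme: GradientScheme) -> DwiImage:
    """Noiseless DWI signal S_i = s0 * exp(-b_i g_i' D g_i) per voxel.

    Background voxels (zero tensor *and* zero everywhere is fine — the
    brain is wherever the field is nonzero) receive 0 in every volume.
    """
    if s0 <= 0:
        raise ValidationError("s0 must be positive")
    if np.any(scheme.bvals < 0):
        raise ValidationError("negative b-value")
    comps = field.components
    brain = np.any(comps != 0, axis=-1)
    g = scheme.bvecs  # (V, 3)
    b = scheme.bvals  # (V,)
    # g' D g expanded over the 6 stored components
    quad = (
        np.multiply.outer(comps[..., 0], g[:, 0] ** 2)
        + np.multiply.outer(comps[..., 1], g[:, 1] ** 2)
        + np.multiply.outer(comps[..., 2], g[:, 2] ** 2)
        + 2 * np.multiply.outer(comps[..., 3], g[:, 0] * g[:, 1])
        + 2 * np.multiply.outer(comps[..., 4], g[:, 0] * g[:, 2])
        + 2 * np.multiply.outer(comps[..., 5], g[:, 1] * g[:, 2])
    )
    signal = s0 * np.exp(-b * quad)
    signal[~brain] = 0.0
    return DwiImage(signal, field.voxel_size, scheme)


def add_rician_noise(image: DwiImage, sigma: float, seed: int) -> DwiImage:
    """Magnitude-MRI noise: S -> sqrt((S + n1)^2 + n2^2) with n1, n2
    i.i.d. zero-mean Gaussians of width ``sigma``.  Deterministic per seed."""
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    if sigma == 0:
        return image
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, image.data.shape)
    n2 = rng.normal(0.0, sigma, image.data.shape)
    noisy = np.sqrt((image.data + n1) ** 2 + n2**2)
    return DwiImage(noisy, image.voxel_size, image.scheme)


def _lesion_center(
    rng: np.random.Generator, grid_shape: tuple[int, int, int]
) -> tuple[int, int, int]:
    """Jittered lesion center well inside the left hemisphere."""
    nx, ny, nz = grid_shape
    cx = int(rng.integers(round(nx * 0.22), round(nx * 0.33)))
    cy = int(rng.integers(round(ny * 0.38), round(ny * 0.62)))
    cz = int(rng.integers(round(nz * 0.35), round(nz * 0.65)))
    return (cx, cy, cz)


def make_subject(
    subject_id: int,
    clinical_class: int,
    params: PhantomParams,
    seed: int,
    noiseless: bool = False,
    keep_tensor_field: bool = False,
) -> SyntheticSubject:
    """Simulate one subject of the given class from one seed."""
    rng = np.random.default_rng(seed)
    lesions: list[LesionSpec] = []
    if clinical_class == 2:
        lesions = [LesionSpec(_lesion_center(rng, params.grid_shape),
                              params.lesion_radius_mm, "acute",
                              params.acute_adc_scale, params.lesion_fa_scale)]
    elif clinical_class == 3:
        lesions = [LesionSpec(_lesion_center(rng, params.grid_shape),
                              params.lesion_radius_mm, "sequela",
                              params.sequela_adc_scale, params.lesion_fa_scale)]
    elif clinical_class != 1:
        raise ValidationError(f"clinical class must be 1, 2 or 3, got {clinical_class}")

    field, brain, truth = make_tensor_field(
        params.grid_shape, params.voxel_size, params.base_md, params.base_fa,
        lesions, seed,
    )
    dwi = simulate_signal(field, params.s0, params.scheme())
    if not noiseless and params.noise_sigma_frac > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        dwi = add_rician_noise(dwi, params.noise_sigma_frac * params.s0, noise_seed)
    return SyntheticSubject(
        subject_id=subject_id,
        clinical_class=clinical_class,
        dwi=dwi,
        truth_lesion=truth,
        brain_mask=brain,
        seed=seed,
        tensor_field=field if keep_tensor_field else None,
    )


def make_cohort(
    n_normal: int,
    n_acute: int,
    n_sequela: int,
    params: PhantomParams | None = None,
    master_seed: int = 0,
    noiseless: bool = False,
) -> list[SyntheticSubject]:
    """Simulate a cohort; per-subject seeds derive deterministically from
    ``master_seed`` so two calls with equal arguments are voxelwise equal."""
    if min(n_normal, n_acute, n_sequela) < 0:
        raise ValidationError("cohort counts must be non-negative")
    if n_normal + n_acute + n_sequela == 0:
        raise ValidationError("cohort must contain at least one subject")
    params = params or PhantomParams()
    classes = [1] * n_normal + [2] * n_acute + [3] * n_sequela
    seeds = np.random.SeedSequence(master_seed).generate_state(len(classes)) % (2**31 - 1)
    return [
        make_subject(i + 1, cls, params, int(s), noiseless=noiseless)
        for i, (cls, s) in enumerate(zip(classes, seeds))
    ]
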