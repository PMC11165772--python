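"""Synthetic sinus-cavity cohort generator with stored ground truth.

Cavities are superellipse tubes along the AP axis whose per-fraction
semi-axes follow configurable width/height profiles (linearly interpolated
between the 11 profile knots). Male widths are the base profile times a
sex multiplier. Each cavity is voxelized directly in a misoriented frame
(rotation applied analytically before voxelization, so the ground truth
stays exact), together with landmark lines consistent with the applied
misorientation.

Optional internal septa are thin erased walls with a central hole: they
partition the interior like air cells while leaving the outer envelope —
and hence the ground-truth width/height — untouched at the measured
sections, and keep the mask a single connected component.

Everything is driven by a single integer seed; identical spec + seed
yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .core import RigidTransform, TriangleMesh, VoxelVolume, rotation_from_view_angles
from .orientation import HeadLandmarks

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticSinus",
    "generate_cavity",
    "generate_cohort",
    "truth_table",
    "save_cohort",
    "ellipsoid_mesh",
    "superellipse_tube_mesh",
    "voxelize_ellipsoid",
]

FRACTIONS = tuple(range(0, 101, 10))

# Default per-fraction target extents (mm) at 0%,10%,...,100%. These are
# generator conventions shaped to the reported regime: width ~8-12 mm,
# height ~15-18 mm peaking near 40%, aspect ratio rising anterior to
# posterior from ~0.6 toward ~0.9.
DEFAULT_HEIGHT_PROFILE = (
    15.0, 16.0, 17.0, 17.8, 18.0, 17.6, 16.6, 15.2, 13.6, 12.0, 11.0,
)
DEFAULT_AR_PROFILE = (
    0.54, 0.56, 0.58, 0.61, 0.64, 0.68, 0.72, 0.76, 0.80, 0.83, 0.85,
)
DEFAULT_WIDTH_PROFILE = tuple(
    round(h * ar, 2) for h, ar in zip(DEFAULT_HEIGHT_PROFILE, DEFAULT_AR_PROFILE)
)

_SEX_CODES = {"female": 0, "male": 1}
_SIDE_CODES = {"left": 0, "right": 1}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    ``n_subjects_per_sex`` is either one count for both sexes or a
    ``(male, female)`` pair (the study-scale default is (21, 15)).
    """

    n_subjects_per_sex: int | tuple[int, int] = (21, 15)
    length_mean_mm: float = 40.7
    length_sd_mm: float = 5.0
    width_profile: tuple = DEFAULT_WIDTH_PROFILE
    height_profile: tuple = DEFAULT_HEIGHT_PROFILE
    sex_width_multiplier: float = 1.2
    misorientation_sd_deg: tuple = (10.0, 2.0, 2.0)  # sagittal-dominant
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)
    surface_noise_sd_mm: float = 0.0
    septa_count: int = 0
    superellipse_exponent: float = 2.0
    subject_scale_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.width_profile) != 11 or len(self.height_profile) != 11:
            raise ValueError("profiles must have exactly 11 entries (0%..100%)")
        for name in ("length_mean_mm", "length_sd_mm", "surface_noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.width_profile) < 0 or min(self.height_profile) < 0:
            raise ValueError("profile extents must be >= 0")
        if self.sex_width_multiplier <= 0:
            raise ValueError("sex_width_multiplier must be > 0")
        if len(self.misorientation_sd_deg) != 3:
            raise ValueError("misorientation_sd_deg needs 3 values")
        if len(self.voxel_spacing_mm) != 3 or min(self.voxel_spacing_mm) <= 0:
            raise ValueError("voxel_spacing_mm needs 3 positive values")
        if self.septa_count < 0 or self.superellipse_exponent <= 0:
            raise ValueError("septa_count >= 0 and superellipse_exponent > 0")

    def n_subjects(self, sex: str) -> int:
        n = self.n_subjects_per_sex
        if np.isscalar(n):
            return int(n)
        return int(n[0]) if sex == "male" else int(n[1])


@dataclass
class GroundTruth:
    """Analytic truth for one generated sinus."""

    subject: str
    sex: str
    side: str
    true_length_mm: float
    fractions: tuple = FRACTIONS
    width_mm: np.ndarray = field(default_factory=lambda: np.zeros(11))
    height_mm: np.ndarray = field(default_factory=lambda: np.zeros(11))
    aspect_ratio: np.ndarray = field(default_factory=lambda: np.zeros(11))
    misorientation_deg: tuple = (0.0, 0.0, 0.0)  # (sagittal, axial, coronal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "sex": self.sex,
                "side": self.side,
                "fraction": list(self.fractions),
                "W_mm": self.width_mm,
                "H_mm": self.height_mm,
                "AR": self.aspect_ratio,
                "length_mm": self.true_length_mm,
            }
        )


@dataclass
class SyntheticSinus:
    volume: VoxelVolume
    landmarks: HeadLandmarks
    truth: GroundTruth


def _interp_profile(profile, fractions: np.ndarray) -> np.ndarray:
    return np.interp(fractions, np.array(FRACTIONS) / 100.0, np.asarray(profile))


def _rng_for(spec: SyntheticSpec, subject_index: int, sex: str, side: str):
    return np.random.default_rng(
        [spec.seed, subject_index, _SEX_CODES[sex], _SIDE_CODES[side]]
    )


def _noise_field(rng, bounds_lo, bounds_hi, sd_mm: float):
    """Smooth random field over a box; SD ``sd_mm``, clipped at +/-1 SD.

    The clip bounds the surface perturbation so noisy cavities stay
    within two voxels of their noise-free envelope even where two
    boundary extremes are perturbed outward at once.
    """
    cell = 4.0  # mm correlation-ish scale
    axes = [
        np.arange(lo - 2 * cell, hi + 3 * cell, cell)
        for lo, hi in zip(bounds_lo, bounds_hi)
    ]
    white = rng.standard_normal([len(a) for a in axes])
    smooth = ndimage.gaussian_filter(white, sigma=1.0, mode="wrap")
    smooth *= sd_mm / smooth.std()
    np.clip(smooth, -sd_mm, sd_mm, out=smooth)
    return RegularGridInterpolator(
        tuple(axes), smooth, bounds_error=False, fill_value=0.0
    )


def generate_cavity(
    spec: SyntheticSpec, subject_index: int, sex: str, side: str
) -> SyntheticSinus:
    """Generate one voxelized, misoriented cavity with ground truth.

    The aligned cavity runs along +Y from 0 to the sampled length,
    centred on the X = Z = 0 line; the recorded misorientation rotates it
    about its physical centre before voxelization.
    """
    if sex not in _SEX_CODES:
        raise ValueError(f"sex must be male or female, got {sex!r}")
    if side not in _SIDE_CODES:
        raise ValueError(f"side must be left or right, got {side!r}")
    rng = _rng_for(spec, subject_index, sex, side)

    length = max(float(rng.normal(spec.length_mean_mm, spec.length_sd_mm)), 10.0)
    scale = (
        float(np.exp(rng.normal(0.0, spec.subject_scale_sd)))
        if spec.subject_scale_sd > 0
        else 1.0
    )
    width = np.asarray(spec.width_profile, float) * scale
    if sex == "male":
        width = width * spec.sex_width_multiplier
    height = np.asarray(spec.height_profile, float) * scale

    spacing = np.asarray(spec.voxel_spacing_mm, float)
    min_across = min(width.min() / spacing[0], height.min() / spacing[2])
    if min_across < 3.0:
        raise ValueError(
            "voxel spacing too coarse: smallest profile extent spans "
            f"{min_across:.1f} voxels (< 3); refine spacing or widen profiles"
        )

    sag, axi, cor = rng.normal(0.0, np.asarray(spec.misorientation_sd_deg))
    rot = rotation_from_view_angles(sag, axi, cor)
    center = np.array([0.0, length / 2.0, 0.0])

    # grid covering the rotated cavity bounding box
    half_w, half_h = width.max() / 2.0, height.max() / 2.0
    margin = 2.0 + 3.0 * spec.surface_noise_sd_mm
    corners = np.array(
        [
            [sx * half_w, y, sz * half_h]
            for sx in (-1, 1)
            for y in (0.0, length)
            for sz in (-1, 1)
        ]
    )
    moved = (corners - center) @ rot.T + center
    lo = moved.min(axis=0) - margin
    hi = moved.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    # sub-voxel grid dither: real scans sample at arbitrary phase relative
    # to the anatomy; without it profile extremes sit knife-edge on
    # lattice planes and are clipped identically in every cavity
    origin = lo - rng.uniform(0.0, 1.0, 3) * spacing

    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    world = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    aligned = (world - center) @ rot + center  # rot^-1 = rot.T applied rowwise

    frac = np.clip(aligned[:, 1] / length, 0.0, 1.0)
    a = _interp_profile(width, frac) / 2.0
    b = _interp_profile(height, frac) / 2.0
    p = spec.superellipse_exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (
            np.abs(aligned[:, 0] / a) ** p + np.abs(aligned[:, 2] / b) ** p
        ) ** (1.0 / p)
    in_length = (aligned[:, 1] >= 0.0) & (aligned[:, 1] <= length)

    if spec.surface_noise_sd_mm > 0:
        noise = _noise_field(rng, lo, hi, spec.surface_noise_sd_mm)
        r_planar = np.hypot(aligned[:, 0], aligned[:, 2])
        # radial mm distance to the noise-free boundary along the point's ray
        with np.errstate(divide="ignore", invalid="ignore"):
            radial_mm = np.where(rho > 0, (rho - 1.0) * r_planar / rho, -1.0)
        inside = (radial_mm <= noise(aligned)) & in_length
    else:
        inside = (rho <= 1.0) & in_length

    mask = inside.reshape(tuple(shape))

    if spec.septa_count > 0:
        wall = max(0.6, 0.6 * spacing[1])
        hole_rho = 0.35
        for s in range(1, spec.septa_count + 1):
            # offset from the measured 10% fractions
            f_s = np.clip(s / (spec.septa_count + 1.0) + 0.045, 0.05, 0.95)
            y_s = f_s * length
            erase = (
                (np.abs(aligned[:, 1] - y_s) < wall) & (rho >= hole_rho) & inside
            )
            mask = mask & ~erase.reshape(tuple(shape))

    volume = VoxelVolume(mask, spacing, origin)

    aligned_landmarks = HeadLandmarks(
        cranial_base=[[0.0, -10.0, half_h + 8.0], [0.0, length + 10.0, half_h + 8.0]],
        nasal_septum=[[0.0, -15.0, -half_h - 5.0], [0.0, -15.0, half_h + 10.0]],
    )

    def _move(pts):
        return (np.asarray(pts) - center) @ rot.T + center

    landmarks = HeadLandmarks(
        _move(aligned_landmarks.cranial_base), _move(aligned_landmarks.nasal_septum)
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.where(height > 0, width / height, np.nan)
    truth = GroundTruth(
        subject=f"{sex[0]}{subject_index:03d}",
        sex=sex,
        side=side,
        true_length_mm=length,
        width_mm=width,
        height_mm=height,
        aspect_ratio=ar,
        misorientation_deg=(float(sag), float(axi), float(cor)),
    )
    return SyntheticSinus(volume, landmarks, truth)


def generate_cohort(spec: SyntheticSpec) -> tuple[list[SyntheticSinus], pd.DataFrame]:
    """Two sinuses (left, right) per subject for each sex.

    Returns the generated sinuses and the combined ground-truth table
    (one row per subject/side/fraction).
    """
    if spec.n_subjects("male") < 1 or spec.n_subjects("female") < 1:
        raise ValueError("need at least one subject per sex")
    sinuses = []
    for sex in ("male", "female"):
        for idx in range(spec.n_subjects(sex)):
            for side in ("left", "right"):
                sinuses.append(generate_cavity(spec, idx, sex, side))
    return sinuses, truth_table(sinuses)


def truth_table(sinuses: list[SyntheticSinus]) -> pd.DataFrame:
    return pd.concat(
        [s.truth.to_frame() for s in sinuses], ignore_index=True
    )


def save_cohort(sinuses: list[SyntheticSinus], out_dir: str | Path) -> pd.DataFrame:
    """Write masks (.nii.gz), landmarks (JSON) and the truth CSV to a dir."""
    from .io import save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in sinuses:
        stem = f"{s.truth.subject}_{s.truth.side}"
        save_mask(s.volume, out / f"{stem}.nii.gz")
        s.landmarks.to_json(out / f"{stem}.landmarks.json")
    table = truth_table(sinuses)
    table.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")
    return table


def misorientation_transform(truth: GroundTruth) -> RigidTransform:
    s, a, c = truth.misorientation_deg
    return RigidTransform(s, a, c)


def aligned_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of the spec with misorientation and noise switched off."""
    return replace(
        spec, misorientation_sd_deg=(0.0, 0.0, 0.0), surface_noise_sd_mm=0.0
    )


# ---------------------------------------------------------------------------
# analytic mesh primitives (exact oracles for the measurement pipeline)


def ellipsoid_mesh(
    semi_axes, center=(0.0, 0.0, 0.0), n_theta: int = 96, n_phi: int = 48
) -> TriangleMesh:
    """Closed UV-sphere mesh scaled to an ellipsoid."""
    ax = np.asarray(semi_axes, float)
    ctr = np.asarray(center, float)
    phis = np.linspace(0.0, np.pi, n_phi + 1)[1:-1]
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ring = np.array(
        [
            [np.sin(p) * np.cos(t), np.sin(p) * np.sin(t), np.cos(p)]
            for p in phis
            for t in thetas
        ]
    )
    verts = np.vstack([[0.0, 0.0, 1.0], ring, [0.0, 0.0, -1.0]]) * ax + ctr
    faces = []
    top, bottom = 0, 1 + len(ring)
    for j in range(n_theta):
        faces.append([top, 1 + j, 1 + (j + 1) % n_theta])
    for i in range(len(phis) - 1):
        r0, r1 = 1 + i * n_theta, 1 + (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    last = 1 + (len(phis) - 1) * n_theta
    for j in range(n_theta):
        faces.append([bottom, last + (j + 1) % n_theta, last + j])
    return TriangleMesh(verts, np.asarray(faces))


def superellipse_tube_mesh(
    width_profile,
    height_profile,
    length: float,
    exponent: float = 2.0,
    n_theta: int = 128,
    n_y: int = 81,
) -> TriangleMesh:
    """Closed tube mesh matching the generator's analytic cavity."""
    w = np.asarray(width_profile, float)
    h = np.asarray(height_profile, float)
    ys = np.linspace(0.0, length, n_y)
    fr = ys / length
    a = _interp_profile(w, fr) / 2.0
    b = _interp_profile(h, fr) / 2.0
    t = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    # superellipse parameterization
    cx = np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / exponent)
    cz = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / exponent)
    verts, faces = [], []
    for i, y in enumerate(ys):
        ring = np.stack([a[i] * cx, np.full(n_theta, y), b[i] * cz], axis=1)
        verts.append(ring)
    verts = np.vstack(verts)
    for i in range(n_y - 1):
        r0, r1 = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    # end caps (fans to ring centroids)
    front = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, 0.0]], [[0.0, length, 0.0]]])
    back = front + 1
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([front, jn, j])
        last = (n_y - 1) * n_theta
        faces.append([back, last + j, last + jn])
    return TriangleMesh(verts, np.asarray(faces))


def voxelize_ellipsoid(
    semi_axes, spacing=(1.0, 1.0, 1.0), margin: float = 2.0
) -> VoxelVolume:
    """Binary voxelization of an origin-centred ellipsoid.

    Samples at cell centres (half-voxel grid offset) so the 0.5-level
    isosurface sits on the analytic boundary on average.
    """
    ax = np.asarray(semi_axes, float)
    sp = np.asarray(spacing, float)
    lo = -ax - margin + sp / 2.0
    shape = np.ceil(2 * (ax + margin) / sp).astype(int)
    coords = [lo[d] + np.arange(shape[d]) * sp[d] for d in range(3)]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    mask = (gx / ax[0]) ** 2 + (gy / ax[1]) ** 2 + (gz / ax[2]) ** 2 <= 1.0
    return VoxelVolume(mask, sp, lo)
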