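"""Landmark-based reorientation to the standard head coordinate convention.

Two labelled landmark lines drive the alignment: the cranial-base line
(runs anteroposteriorly; seen horizontal in the sagittal and coronal views
once aligned) and the nasal-septum line (runs superoinferiorly; seen
vertical in the axial and coronal views once aligned).

:func:`compute_reorientation` returns the *misorientation* of the scan —
its per-view angle fields are the rotations observed in the sagittal,
axial and coronal views relative to the aligned convention. Applying the
transform's :meth:`~sinusect.core.RigidTransform.inverse` aligns the data;
:func:`reorient` does exactly that.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import RigidTransform, TriangleMesh, VoxelVolume

__all__ = [
    "HeadLandmarks",
    "DegenerateLandmarksError",
    "compute_reorientation",
    "apply_transform",
    "reorient",
    "report_misorientation",
    "aggregate_misorientation",
]

# Aligned reference directions for the two landmark lines.
_CRANIAL_BASE_DIR = np.array([0.0, 1.0, 0.0])  # anteroposterior
_NASAL_SEPTUM_DIR = np.array([0.0, 0.0, 1.0])  # superoinferior

_MIN_LINE_LENGTH_MM = 1.0


class DegenerateLandmarksError(ValueError):
    """Raised when landmark lines cannot define an orientation."""


@dataclass
class HeadLandmarks:
    """Labelled landmark points, millimetre coordinates.

    Each line needs at least two non-coincident points; more points are
    fitted by total least squares.
    """

    cranial_base: np.ndarray
    nasal_septum: np.ndarray
    coronal_check: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.cranial_base = np.asarray(self.cranial_base, float).reshape(-1, 3)
        self.nasal_septum = np.asarray(self.nasal_septum, float).reshape(-1, 3)
        if self.coronal_check is not None:
            self.coronal_check = np.asarray(self.coronal_check, float).reshape(-1, 3)
        for name, pts in (
            ("cranial_base", self.cranial_base),
            ("nasal_septum", self.nasal_septum),
        ):
            if len(pts) < 2:
                raise DegenerateLandmarksError(f"{name}: need >= 2 points")
            span = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
            if span <= _MIN_LINE_LENGTH_MM:
                raise DegenerateLandmarksError(
                    f"{name}: points span {span:.3f} mm (<= {_MIN_LINE_LENGTH_MM} mm)"
                )

    def transformed(self, transform: RigidTransform) -> "HeadLandmarks":
        return HeadLandmarks(
            transform.apply_points(self.cranial_base),
            transform.apply_points(self.nasal_septum),
            None
            if self.coronal_check is None
            else transform.apply_points(self.coronal_check),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "convention": "mm; +X mediolateral, +Y anteroposterior, +Z superoinferior",
            "cranial_base": self.cranial_base.tolist(),
            "nasal_septum": self.nasal_septum.tolist(),
        }
        if self.coronal_check is not None:
            payload["coronal_check"] = self.coronal_check.tolist()
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HeadLandmarks":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["cranial_base"],
            payload["nasal_septum"],
            payload.get("coronal_check"),
        )


def _fit_line_direction(points: np.ndarray, label: str) -> np.ndarray:
    """Total-least-squares line direction (unit vector)."""
    centered = points - points.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= 1e-12:
        raise DegenerateLandmarksError(f"{label}: points are coincident")
    return vt[0]


def compute_reorientation(landmarks: HeadLandmarks) -> RigidTransform:
    """Recover the scan misorientation from the landmark lines.

    The returned transform maps aligned coordinates to the observed ones;
    its angle fields are the per-view misorientation. Apply ``.inverse()``
    to bring data into the aligned convention.
    """
    u = _fit_line_direction(landmarks.cranial_base, "cranial_base")
    if u @ _CRANIAL_BASE_DIR < 0:  # assume misorientation < 90 deg
        u = -u
    v = _fit_line_direction(landmarks.nasal_septum, "nasal_septum")
    if v @ _NASAL_SEPTUM_DIR < 0:
        v = -v
    # Orthogonalize the septum direction against the cranial-base direction.
    v_perp = v - (v @ u) * u
    norm = np.linalg.norm(v_perp)
    if norm < 1e-6:
        raise DegenerateLandmarksError(
            "nasal_septum line is parallel to the cranial_base line"
        )
    if norm < 0.5:
        warnings.warn(
            "nasal_septum and cranial_base lines are far from perpendicular "
            f"(|sin| = {norm:.3f}); orientation may be unreliable",
            stacklevel=2,
        )
    v_perp /= norm
    # Misorientation R maps (+Y -> u, +Z -> v_perp, +X -> u x v_perp).
    rot = np.column_stack([np.cross(u, v_perp), u, v_perp])
    return RigidTransform.from_matrix(rot)


def _resample_volume(volume: VoxelVolume, transform: RigidTransform) -> VoxelVolume:
    """Rotate a volume about its physical centre onto a new enclosing grid.

    Nearest-neighbour for boolean masks (mask preserving), linear otherwise.
    The output grid is recomputed from the transformed bounding box, so no
    foreground is ever clipped.
    """
    rot = transform.rotation
    spacing = volume.spacing
    center = volume.origin + (np.array(volume.shape) - 1) * spacing / 2.0
    bounds = volume.physical_bounds()
    corners = np.array(
        [[bounds[i, 0], bounds[j, 1], bounds[k, 2]] for i in range(2)
         for j in range(2) for k in range(2)]
    )
    moved = (corners - center) @ rot.T + center + transform.translation
    lo = moved.min(axis=0) - spacing
    hi = moved.max(axis=0) + spacing
    new_shape = np.maximum(np.round((hi - lo) / spacing).astype(int) + 1, 1)
    new_origin = lo

    # Output voxel o maps back to input index A @ o + b.
    inv = rot.T
    scale = np.diag(spacing)
    inv_scale = np.diag(1.0 / spacing)
    matrix = inv_scale @ inv @ scale
    offset = inv_scale @ (
        inv @ (new_origin - center - transform.translation) + center - volume.origin
    )
    order = 0 if volume.is_mask else 1
    resampled = ndimage.affine_transform(
        volume.data.astype(np.uint8) if volume.is_mask else volume.data,
        matrix,
        offset=offset,
        output_shape=tuple(new_shape),
        order=order,
        mode="constant",
        cval=0,
    )
    if volume.is_mask:
        resampled = resampled.astype(bool)
    return VoxelVolume(resampled, spacing.copy(), new_origin)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid transform to a mesh, volume or landmark set.

    Meshes and landmarks are transformed exactly; volumes are resampled
    (nearest-neighbour for masks) onto a grid enclosing the moved data.
    Identity transforms return the input unchanged.
    """
    if transform.is_identity():
        return obj
    if isinstance(obj, TriangleMesh):
        return obj.transformed(transform)
    if isinstance(obj, HeadLandmarks):
        return obj.transformed(transform)
    if isinstance(obj, VoxelVolume):
        return _resample_volume(obj, transform)
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


def reorient(obj, landmarks: HeadLandmarks):
    """Align an object using its landmarks; returns (aligned, misorientation)."""
    mis = compute_reorientation(landmarks)
    return apply_transform(obj, mis.inverse()), mis


def report_misorientation(transform: RigidTransform) -> dict[str, float]:
    """Per-view misorientation magnitudes in degrees."""
    s, a, c = transform.angles()
    return {
        "sagittal_deg": abs(s),
        "axial_deg": abs(a),
        "coronal_deg": abs(c),
    }


def aggregate_misorientation(
    transforms: list[RigidTransform],
) -> dict[str, dict[str, float]]:
    """Cohort mean +/- SD of per-view misorientation magnitudes."""
    if not transforms:
        raise ValueError("no transforms to aggregate")
    records = np.array(
        [
            [r["sagittal_deg"], r["axial_deg"], r["coronal_deg"]]
            for r in map(report_misorientation, transforms)
        ]
    )
    out = {}
    for i, plane in enumerate(("sagittal", "axial", "coronal")):
        out[plane] = {
            "mean_deg": float(records[:, i].mean()),
            "sd_deg": float(records[:, i].std(ddof=1)) if len(records) > 1 else 0.0,
        }
    return out
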