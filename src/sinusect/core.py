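"""Core geometric types shared by all pipeline stages.

Axis convention (fixed throughout the package):

* ``+X`` — mediolateral (left to right)
* ``+Y`` — anteroposterior (anterior to posterior); sections are cut
  perpendicular to this axis
* ``+Z`` — superoinferior (inferior to superior)

Rotations are named by the anatomical *view* in which they are observed:

* ``sagittal``  — rotation seen in the sagittal (YZ) view, i.e. about X
* ``axial``     — rotation seen in the axial (XY) view, i.e. about Z
* ``coronal``   — rotation seen in the coronal (XZ) view, i.e. about Y

A :class:`RigidTransform` composes these in the fixed order
coronal -> axial -> sagittal (coronal applied first):
``R = Rx(sagittal) @ Rz(axial) @ Ry(coronal)``.

All coordinates are millimetres; all interface angles are degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPOSITION_ORDER = "coronal-axial-sagittal"


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_from_view_angles(
    sagittal_deg: float, axial_deg: float, coronal_deg: float
) -> np.ndarray:
    """Rotation matrix for per-view angles, coronal applied first."""
    s, a, c = np.deg2rad([sagittal_deg, axial_deg, coronal_deg])
    return _rx(s) @ _rz(a) @ _ry(c)


def view_angles_from_rotation(rot: np.ndarray) -> tuple[float, float, float]:
    """Invert :func:`rotation_from_view_angles`.

    Valid away from the gimbal lock at axial = +/-90 deg, far outside the
    misorientation range this package deals with (<= ~20 deg).
    """
    rot = np.asarray(rot, dtype=float)
    axial = -np.arcsin(np.clip(rot[0, 1], -1.0, 1.0))
    coronal = np.arctan2(rot[0, 2], rot[0, 0])
    sagittal = np.arctan2(rot[2, 1], rot[1, 1])
    return (
        float(np.rad2deg(sagittal)),
        float(np.rad2deg(axial)),
        float(np.rad2deg(coronal)),
    )


@dataclass
class RigidTransform:
    """Rigid transform expressed as per-view rotation angles + translation.

    ``apply_points`` maps ``p -> R p + t`` with
    ``R = Rx(sagittal) @ Rz(axial) @ Ry(coronal)``.
    """

    sagittal_deg: float = 0.0
    axial_deg: float = 0.0
    coronal_deg: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    order: str = COMPOSITION_ORDER

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.order != COMPOSITION_ORDER:
            raise ValueError(f"unsupported composition order: {self.order!r}")

    @property
    def rotation(self) -> np.ndarray:
        return rotation_from_view_angles(
            self.sagittal_deg, self.axial_deg, self.coronal_deg
        )

    @classmethod
    def from_matrix(
        cls, rot: np.ndarray, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        rot = np.asarray(rot, dtype=float)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(rot), 1.0, atol=1e-8
        ):
            raise ValueError("rotation part must be orthonormal with det +1")
        s, a, c = view_angles_from_rotation(rot)
        t = np.zeros(3) if translation is None else translation
        return cls(s, a, c, t)

    def inverse(self) -> "RigidTransform":
        rot = self.rotation
        return RigidTransform.from_matrix(rot.T, -rot.T @ self.translation)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def angles(self) -> tuple[float, float, float]:
        """(sagittal, axial, coronal) in degrees, signed."""
        return (self.sagittal_deg, self.axial_deg, self.coronal_deg)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.sagittal_deg) <= tol
            and abs(self.axial_deg) <= tol
            and abs(self.coronal_deg) <= tol
            and np.all(np.abs(self.translation) <= tol)
        )


@dataclass
class VoxelVolume:
    """3D voxel grid with physical spacing and origin.

    ``data[i, j, k]`` lives at world position ``origin + (i, j, k) * spacing``
    with axes (X, Y, Z) == (ML, AP, SI).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_mask(self) -> bool:
        return self.data.dtype == bool

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def physical_bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] voxel-centre world coordinates."""
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return np.stack([self.origin, hi])

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimetre coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    side: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces) and self.faces.min() < 0:
            raise ValueError("negative face index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) [min, max] of vertex coordinates."""
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def extents(self) -> np.ndarray:
        b = self.bounds()
        return b[1] - b[0]

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def remove_degenerate_faces(self, area_tol: float = 1e-9) -> "TriangleMesh":
        keep = self.face_areas() > area_tol
        return TriangleMesh(self.vertices, self.faces[keep], self.side)

    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (mm^3); abs of the sum."""
        v = self.vertices[self.faces]
        return float(
            abs(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)
        )

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(
            transform.apply_points(self.vertices), self.faces.copy(), self.side
        )

    def mirrored_x(self) -> "TriangleMesh":
        """Reflect across the mid-sagittal (X = 0) plane, flipping winding."""
        verts = self.vertices.copy()
        verts[:, 0] *= -1.0
        return TriangleMesh(verts, self.faces[:, ::-1].copy(), self.side)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.side)
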