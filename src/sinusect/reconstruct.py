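"""Cavity surface reconstruction: isosurfacing and boundary clipping.

The binary cavity mask is isosurfaced at the 0.5 level (marching cubes),
the largest connected surface component is kept, and everything outside
the anatomical boundary surfaces — superior (cranial base), lateral
(periorbital) and medial (middle turbinate) — is removed. The inferior
side is deliberately never clipped: the cavity's own lower envelope is
the inferior limit.

Boundary surfaces are explicit geometric inputs: oriented planes or
single-valued heightfields, each with an inside direction. Clipping works
on any surface expressible as a signed scalar field (negative inside),
evaluated at mesh vertices with edge crossings found by linear
interpolation — exact for planes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage import measure

from .core import TriangleMesh, VoxelVolume

__all__ = [
    "PlaneBoundary",
    "HeightfieldBoundary",
    "BoundarySpec",
    "EmptyMaskError",
    "EmptyClipError",
    "extract_isosurface",
    "clip_by_boundary",
    "clip_by_field",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class EmptyMaskError(ValueError):
    """Raised when a cavity mask contains no foreground voxels."""


class EmptyClipError(ValueError):
    """Raised when a boundary excludes the entire cavity."""


@dataclass
class PlaneBoundary:
    """Oriented plane; ``normal`` points *outward* (away from the cavity).

    A point ``p`` is inside when ``(p - point) . normal <= 0``.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float).reshape(3)
        normal = np.asarray(self.normal, float).reshape(3)
        length = np.linalg.norm(normal)
        if length <= 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = normal / length

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def to_dict(self) -> dict:
        return {
            "type": "plane",
            "point": self.point.tolist(),
            "normal": self.normal.tolist(),
        }


@dataclass
class HeightfieldBoundary:
    """Single-valued surface ``coord[axis] = f(other two coords)``.

    ``inside_sign=+1`` keeps points *below* the surface (coord <= f),
    ``-1`` keeps points above. Heights are sampled on a regular grid and
    interpolated bilinearly; queries outside the grid extrapolate from the
    nearest cell.
    """

    axis: str
    grid_u: np.ndarray
    grid_v: np.ndarray
    heights: np.ndarray
    inside_sign: int = 1

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError("axis must be one of x, y, z")
        if self.inside_sign not in (1, -1):
            raise ValueError("inside_sign must be +1 or -1")
        self.grid_u = np.asarray(self.grid_u, float)
        self.grid_v = np.asarray(self.grid_v, float)
        self.heights = np.asarray(self.heights, float)
        if self.heights.shape != (len(self.grid_u), len(self.grid_v)):
            raise ValueError("heights shape must be (len(grid_u), len(grid_v))")
        self._interp = RegularGridInterpolator(
            (self.grid_u, self.grid_v),
            self.heights,
            bounds_error=False,
            fill_value=None,  # linear extrapolation
        )

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        k = _AXES[self.axis]
        uv_axes = [a for a in range(3) if a != k]
        f = self._interp(pts[:, uv_axes])
        return self.inside_sign * (pts[:, k] - f)

    def to_dict(self) -> dict:
        return {
            "type": "heightfield",
            "axis": self.axis,
            "grid_u": self.grid_u.tolist(),
            "grid_v": self.grid_v.tolist(),
            "heights": self.heights.tolist(),
            "inside_sign": self.inside_sign,
        }


def _boundary_from_dict(d: dict):
    if d["type"] == "plane":
        return PlaneBoundary(d["point"], d["normal"])
    if d["type"] == "heightfield":
        return HeightfieldBoundary(
            d["axis"], d["grid_u"], d["grid_v"], d["heights"], d.get("inside_sign", 1)
        )
    raise ValueError(f"unknown boundary type {d['type']!r}")


@dataclass
class BoundarySpec:
    """Anatomical clipping boundaries; any of the three may be absent."""

    upper: PlaneBoundary | HeightfieldBoundary | None = None
    lateral: PlaneBoundary | HeightfieldBoundary | None = None
    medial: PlaneBoundary | HeightfieldBoundary | None = None

    def surfaces(self):
        return [
            (name, s)
            for name, s in (
                ("upper", self.upper),
                ("lateral", self.lateral),
                ("medial", self.medial),
            )
            if s is not None
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: s.to_dict() if s is not None else None
            for name, s in (
                ("upper", self.upper),
                ("lateral", self.lateral),
                ("medial", self.medial),
            )
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundarySpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            **{
                k: (_boundary_from_dict(v) if v else None)
                for k, v in payload.items()
                if k in ("upper", "lateral", "medial")
            }
        )


def _largest_component(mesh: TriangleMesh, warn_fraction: float = 0.1) -> TriangleMesh:
    """Keep faces of the largest vertex-connected surface component."""
    nv = mesh.n_vertices
    edges = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(nv, nv)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp == 1:
        return mesh
    face_labels = labels[mesh.faces[:, 0]]
    sizes = np.bincount(face_labels, minlength=n_comp)
    keep_label = int(np.argmax(sizes))
    large = sizes[(sizes > warn_fraction * sizes[keep_label])]
    if len(large) > 1:
        warnings.warn(
            f"mask yielded {len(large)} large surface components "
            f"(face counts {sorted(large.tolist(), reverse=True)}); "
            "keeping the largest",
            stacklevel=3,
        )
    keep = face_labels == keep_label
    used = np.unique(mesh.faces[keep])
    remap = np.full(nv, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[mesh.faces[keep]], mesh.side)


def extract_isosurface(
    volume: VoxelVolume, side: str | None = None, smooth_sigma: float = 0.5
) -> TriangleMesh:
    """Isosurface a binary mask at the 0.5 level, in mm coordinates.

    The mask is zero-padded first so the surface is closed even when
    foreground touches the grid edge. ``smooth_sigma`` (voxels) applies a
    light Gaussian to the binary field before contouring — anti-aliased
    isosurfacing that places the 0.5 level with sub-voxel accuracy instead
    of quantizing it to half-voxel positions; 0 disables it. Only the
    largest connected surface component is returned; additional components
    above 10% of its size trigger a warning.
    """
    mask = volume.data.astype(bool)
    if not mask.any():
        raise EmptyMaskError("cavity mask is empty")
    pad = 2 if smooth_sigma > 0 else 1
    padded = np.pad(mask, pad).astype(np.float32)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma)
        # structures a voxel thin can be smoothed below the level; fall
        # back to the raw binary field there
        padded = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(volume.spacing)
    )
    verts = verts + (volume.origin - pad * volume.spacing)
    mesh = TriangleMesh(verts, faces, side).remove_degenerate_faces()
    return _largest_component(mesh)


def clip_by_field(mesh: TriangleMesh, field_values: np.ndarray) -> TriangleMesh:
    """Clip a mesh by a per-vertex scalar field, keeping field <= 0.

    Crossing edges are split at the linear zero of the field (exact for
    planar fields); cut faces are re-triangulated. The result may be open
    along the cut loops.
    """
    tol = 1e-9
    f = np.asarray(field_values, float)
    inside = f <= tol
    face_in = inside[mesh.faces]
    n_in = face_in.sum(axis=1)

    keep_faces = mesh.faces[n_in == 3]
    cut_faces = mesh.faces[(n_in == 1) | (n_in == 2)]

    new_verts = [mesh.vertices]
    next_idx = mesh.n_vertices
    edge_cache: dict[tuple[int, int], int] = {}
    tris: list[tuple[int, int, int]] = [tuple(t) for t in keep_faces]

    def crossing(a: int, b: int) -> int:
        nonlocal next_idx
        key = (a, b) if a < b else (b, a)
        idx = edge_cache.get(key)
        if idx is None:
            t = f[a] / (f[a] - f[b])
            p = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
            new_verts.append(p[None, :])
            idx = next_idx
            edge_cache[key] = idx
            next_idx += 1
        return idx

    for tri in cut_faces:
        ins = [v for v in tri if inside[v]]
        # rotate so the face keeps its winding with the odd vertex first
        a, b, c = tri
        if len(ins) == 1:
            while not inside[a]:
                a, b, c = b, c, a
            pab, pca = crossing(a, b), crossing(c, a)
            tris.append((a, pab, pca))
        else:
            while inside[a]:
                a, b, c = b, c, a
            # a outside; b, c inside
            pab, pca = crossing(a, b), crossing(c, a)
            tris.append((b, c, pca))
            tris.append((b, pca, pab))

    if not tris:
        raise EmptyClipError("boundary excludes entire cavity")
    verts = np.vstack(new_verts)
    faces = np.asarray(tris, dtype=np.int64)
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(verts[used], remap[faces], mesh.side)
    return out.remove_degenerate_faces()


def clip_by_boundary(mesh: TriangleMesh, boundary: BoundarySpec) -> TriangleMesh:
    """Remove mesh area outside the anatomical boundary surfaces.

    Surfaces are applied in sequence (upper, lateral, medial); each clip
    keeps the inside half. Boundaries entirely outside the mesh are no-ops.
    """
    out = mesh
    for name, surface in boundary.surfaces():
        values = surface.signed_distance(out.vertices)
        if np.all(values <= 1e-9):
            continue
        if np.all(values > 1e-9):
            raise EmptyClipError(f"{name} boundary excludes entire cavity")
        out = clip_by_field(out, values)
    return out
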