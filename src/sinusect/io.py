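"""File formats: NIfTI masks, PLY/STL meshes, profile CSV schema."""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import TriangleMesh, VoxelVolume

PROFILE_COLUMNS = [
    "subject",
    "sex",
    "side",
    "fraction",
    "W_mm",
    "H_mm",
    "AR",
    "length_mm",
]


def save_mask(volume: VoxelVolume, path: str | Path) -> None:
    """Write a mask/volume as NIfTI; spacing and origin go into the affine."""
    data = volume.data.astype(np.uint8) if volume.is_mask else volume.data
    nib.save(nib.Nifti1Image(data, volume.affine()), str(path))


def load_mask(path: str | Path, as_mask: bool = True) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(affine[:3, :3], np.diag(spacing), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned NIfTI affines are supported")
    if as_mask:
        data = data > 0.5
    return VoxelVolume(data, spacing, affine[:3, 3])


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _save_ply(mesh, path)
    elif path.suffix.lower() == ".stl":
        _save_stl(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")


def load_mesh(path: str | Path, side: str | None = None) -> TriangleMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _load_ply(path, side)
    raise ValueError(f"unsupported mesh format: {path.suffix!r} (read PLY only)")


def _save_ply(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment units mm\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _load_ply(path: Path, side: str | None) -> TriangleMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_verts = n_faces = 0
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise ValueError(f"{path}: only ascii PLY supported")
            if line.startswith("element vertex"):
                n_verts = int(line.split()[-1])
            elif line.startswith("element face"):
                n_faces = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.array(
            [fh.readline().split()[:3] for _ in range(n_verts)], dtype=float
        )
        faces = np.array(
            [fh.readline().split()[1:4] for _ in range(n_faces)], dtype=np.int64
        )
    return TriangleMesh(verts, faces, side)


def _save_stl(mesh: TriangleMesh, path: Path) -> None:
    tris = mesh.vertices[mesh.faces].astype(np.float32)
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(
        normals, lengths, out=np.zeros_like(normals), where=lengths > 0
    )
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", mesh.n_faces))
        for n, t in zip(normals, tris):
            fh.write(n.astype(np.float32).tobytes())
            fh.write(t.astype(np.float32).tobytes())
            fh.write(b"\0\0")


def validate_profile_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the profile CSV schema; returns the table for chaining."""
    missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    if table["fraction"].min() < 0 or table["fraction"].max() > 100:
        raise ValueError("fractions must lie in [0, 100] percent")
    bad_sex = set(table["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    return table


def save_profiles(table: pd.DataFrame, path: str | Path) -> None:
    validate_profile_table(table)
    table.to_csv(path, index=False, columns=PROFILE_COLUMNS, float_format="%.6g")


def load_profiles(path: str | Path) -> pd.DataFrame:
    return validate_profile_table(pd.read_csv(path))
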