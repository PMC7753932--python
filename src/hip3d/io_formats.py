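"""Containers and file I/O for volumes, label maps, meshes and tables.

NIfTI is the canonical volume format.  World coordinates are
``origin + index * spacing`` in the package's anatomical frame
(:data:`hip3d.geometry.ANATOMICAL_FRAME`); affines may carry axis
permutations/flips, which are normalised to the canonical orientation on
read, but oblique rotations are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import ANATOMICAL_FRAME

MIN_SHAPE = (8, 8, 8)


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel spacing and world origin (mm)."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_convention: str = ANATOMICAL_FRAME

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.axis_convention != ANATOMICAL_FRAME:
            raise ValueError(
                f"axis convention {self.axis_convention!r} != {ANATOMICAL_FRAME!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.spacing_mm


@dataclass
class LabelMap(VolumeImage):
    """Integer grid with labels {0 background, 1 femur, 2 acetabulum}."""

    LABELS = {0: "background", 1: "femur", 2: "acetabulum"}

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded):
                raise ValueError("label map values must be integers")
            self.values = rounded.astype(np.uint8)


@dataclass
class SurfaceMesh:
    """Triangulated surface; vertices in world mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices @ np.asarray(rotation).T + np.asarray(translation),
                           self.faces.copy())


# ---------------------------------------------------------------------------
# volumes

def _check_affine(affine: np.ndarray) -> None:
    rot = affine[:3, :3]
    # exactly one nonzero entry per row/column: permutation * flip * spacing
    nz = np.abs(rot) > 1e-6 * max(1.0, np.abs(rot).max())
    if np.any(nz.sum(axis=0) != 1) or np.any(nz.sum(axis=1) != 1):
        raise ValueError("oblique NIfTI affine: only axis permutations/flips supported")


def read_volume(path, label: bool = False) -> VolumeImage:
    """Read a NIfTI volume, reoriented to the canonical anatomical frame."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    _check_affine(img.affine)
    img = nib.as_closest_canonical(img)
    values = np.asanyarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    cls = LabelMap if label else VolumeImage
    return cls(values=values, spacing_mm=spacing, origin_mm=origin)


def write_volume(vol: VolumeImage, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing_mm)
    affine[:3, 3] = vol.origin_mm
    data = vol.values
    if isinstance(vol, LabelMap):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    return read_volume(path, label=True)


# ---------------------------------------------------------------------------
# meshes

_MESH_EXT = {".ply": "ply", ".stl": "stl"}


def read_mesh(path) -> SurfaceMesh:
    ext = Path(path).suffix.lower()
    if ext not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format {ext!r} (use .ply or .stl)")
    m = trimesh.load(str(path), file_type=_MESH_EXT[ext], process=False)
    if isinstance(m, trimesh.Scene):  # pragma: no cover - multi-body files
        m = m.to_mesh()
    if len(m.faces) == 0:
        raise ValueError(f"{path}: empty mesh")
    if ext == ".stl":
        # STL stores free triangles; merge coincident corners back together
        m.merge_vertices()
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def write_mesh(mesh: SurfaceMesh, path, ascii: bool = False) -> None:
    ext = Path(path).suffix.lower()
    if ext not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format {ext!r} (use .ply or .stl)")
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh")
    tm = mesh.as_trimesh()
    if ext == ".stl":
        data = tm.export(file_type="stl_ascii" if ascii else "stl")
    else:
        data = tm.export(file_type="ply", encoding="ascii" if ascii else "binary")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# tables and reports

def read_pairs_csv(path, col_a: str | None = None, col_b: str | None = None
                   ) -> pd.DataFrame:
    """Read paired measurements (method A, method B[, hip id]) from CSV.

    Returns a DataFrame with columns ``a``, ``b`` and ``hip_id``.
    """
    df = pd.read_csv(path)
    numeric_cols = [c for c in df.columns if c not in ("hip_id", "id")]
    if col_a is None or col_b is None:
        if len(numeric_cols) != 2:
            raise ValueError(
                f"{path}: expected exactly two measurement columns, got {numeric_cols}"
            )
        col_a, col_b = numeric_cols
    out = pd.DataFrame({"a": df[col_a], "b": df[col_b]})
    for col in ("a", "b"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if len(bad):
            raise ValueError(f"{path}: non-numeric or missing value in row {bad[0]}")
        out[col] = vals.astype(float)
    if len(out) < 3:
        raise ValueError(f"{path}: need at least 3 pairs, got {len(out)}")
    out["hip_id"] = df["hip_id"] if "hip_id" in df.columns else np.arange(len(out))
    return out


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
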