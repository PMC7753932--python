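"""Periacetabular osteotomy (PAO) simulation.

The acetabular fragment is selected by a sphere cut around the femoral
head center (a single-parameter stand-in for the surgical osteotomy
planes), rigidly rotated about the FHC, and the full morphometry is
recomputed on the reoriented joint, yielding before/after/delta tables
for the coverage-increasing reorientation that the surgery performs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .io_formats import LabelMap, SurfaceMesh
from .morphometry import (
    HeadSphere,
    MorphometryReport,
    extract_articular_patch,
    fit_head_sphere,
    morphometry_report,
)
from .evaluation import extract_surface


@dataclass
class PaoPlan:
    """Fragment rotation in degrees about the anatomical axes (extrinsic
    x-then-y-then-z order) with the FHC as pivot, and the sphere-cut
    radius selecting the fragment."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fragment_radius_mm: float = 45.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rotation_deg = tuple(float(a) for a in self.rotation_deg)
        if max(abs(a) for a in self.rotation_deg) > 60.0:
            self.flags["rotation_exceeds_planning_bound"] = self.rotation_deg

    @property
    def rotation_matrix(self) -> np.ndarray:
        return geometry.euler_xyz_matrix(*self.rotation_deg)


def select_fragment(acetab_mesh: SurfaceMesh, head: HeadSphere, radius_mm: float
                    ) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Split the acetabular surface into (fragment, remainder).

    The fragment is the connected set of faces whose vertices all lie
    within ``radius_mm`` of the FHC, in the component that contains the
    articular surface; the partition of faces is exact.
    """
    if radius_mm <= head.radius_mm:
        raise ValueError("fragment radius must exceed the femoral head radius")
    verts = acetab_mesh.vertices
    d = np.linalg.norm(verts - head.center_mm, axis=1)
    keep = d <= radius_mm
    fmask = keep[acetab_mesh.faces].all(axis=1)
    if not fmask.any():
        raise ValueError("empty fragment: no acetabular faces within the cut radius")
    faces_in = acetab_mesh.faces[fmask]
    # component containing the articular surface = the one with the vertex
    # closest to the head sphere
    from .morphometry import _vertex_components

    comp = _vertex_components(len(verts), faces_in)
    seed_vertex = faces_in.reshape(-1)[
        np.argmin(np.abs(d[faces_in.reshape(-1)] - head.radius_mm))]
    main = comp[seed_vertex]
    sel = comp[faces_in[:, 0]] == main
    frag_faces = faces_in[sel]
    rest_faces = np.vstack([acetab_mesh.faces[~fmask], faces_in[~sel]])

    def _compact(faces):
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(verts[used], remap[faces]) if len(faces) else \
            SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

    return _compact(frag_faces), _compact(rest_faces)


def apply_pao(fragment: SurfaceMesh, plan: PaoPlan, head: HeadSphere) -> SurfaceMesh:
    """Rotate the fragment rigidly about the FHC (an exact isometry)."""
    r = plan.rotation_matrix
    c = head.center_mm
    return SurfaceMesh((fragment.vertices - c) @ r.T + c, fragment.faces.copy())


def _merge(a: SurfaceMesh, b: SurfaceMesh) -> SurfaceMesh:
    if b.n_faces == 0:
        return a
    return SurfaceMesh(np.vstack([a.vertices, b.vertices]),
                       np.vstack([a.faces, b.faces + a.n_vertices]))


def pao_report(labels: LabelMap | None = None, *, plan: PaoPlan,
               femur_mesh: SurfaceMesh | None = None,
               acetab_mesh: SurfaceMesh | None = None,
               fhc_hint_mm=None, smooth_sigma_vox: float = 0.6,
               n_dirs: int = 10000, seed: int = 0):
    """Morphometry before and after the planned reorientation.

    Returns (before, after, deltas) where deltas maps each diagnostic
    parameter to after - before.  The femoral head sphere is fitted once
    and shared, since the femur does not move.
    """
    if labels is not None:
        femur_mesh = extract_surface(labels, 1, smooth_sigma_vox)
        acetab_mesh = extract_surface(labels, 2, smooth_sigma_vox)
        if fhc_hint_mm is None:
            idx = np.argwhere(labels.values == 1)
            fhc_hint_mm = labels.index_to_world(idx).mean(axis=0)
    if femur_mesh is None or acetab_mesh is None:
        raise ValueError("provide a label map or both femur and acetabulum meshes")
    if fhc_hint_mm is None:
        fhc_hint_mm = femur_mesh.vertices.mean(axis=0)
    head = fit_head_sphere(femur_mesh, fhc_hint_mm, seed=seed)
    before = morphometry_report(femur_mesh=femur_mesh, acetab_mesh=acetab_mesh,
                                head=head, n_dirs=n_dirs, seed=seed)
    fragment, remainder = select_fragment(acetab_mesh, head, plan.fragment_radius_mm)
    # sanity: the fragment must carry the articular surface
    extract_articular_patch(fragment, head)
    moved = apply_pao(fragment, plan, head)
    after_mesh = _merge(moved, remainder)
    after = morphometry_report(femur_mesh=femur_mesh, acetab_mesh=after_mesh,
                               head=head, n_dirs=n_dirs, seed=seed)
    from .morphometry import PARAMETERS

    deltas = {p: getattr(after, p) - getattr(before, p) for p in PARAMETERS}
    if plan.flags:
        after.flags.update(plan.flags)
    return before, after, deltas
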