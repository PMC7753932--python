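"""3D hip morphometry from a segmented hip joint.

From femur and acetabulum surfaces the module derives the seven
diagnostic parameters used in hip-preservation planning: acetabular
inclination and anteversion, the lateral center-edge (LCE, Wiberg)
angle, the extrusion index, and total / anterior / posterior femoral
head coverage.  All conventions live in one place:

* frame: +x lateral, +y anterior, +z superior (:mod:`hip3d.geometry`);
* femoral head = sphere fitted to the femur surface (RANSAC + algebraic
  refinement), its center being the FHC;
* articular patch = largest connected acetabular region at joint-space
  distance from the head sphere; the acetabular rim is its open
  boundary loop, and the opening plane is the least-squares plane of
  that loop, normal oriented out of the cup;
* coverage = fraction of quasi-uniform sphere directions whose ray from
  the FHC hits the acetabular surface within a bounded reach; the
  anterior (posterior) coverage is the covered fraction within the
  anterior (posterior) hemisphere of directions, so a symmetric cup has
  anterior = posterior = total;
* LCE / extrusion index are coronal-plane (xz) projections measured at
  the most lateral rim point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import geometry
from .evaluation import extract_surface
from .io_formats import LabelMap, SurfaceMesh

ANATOMICAL_RADIUS_BOUNDS = (15.0, 35.0)  # mm, plausible adult femoral head

#: Report fields compared across methods, in conventional reporting order.
PARAMETERS = (
    "inclination_deg",
    "anteversion_deg",
    "lce_deg",
    "extrusion_index_pct",
    "total_cov_pct",
    "anterior_cov_pct",
    "posterior_cov_pct",
)


@dataclass
class HeadSphere:
    center_mm: np.ndarray
    radius_mm: float
    inlier_fraction: float = 1.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        lo, hi = ANATOMICAL_RADIUS_BOUNDS
        if not (lo <= self.radius_mm <= hi):
            self.flags["radius_outside_anatomical_bounds"] = self.radius_mm


@dataclass
class AcetabularRim:
    """Ordered open-boundary loop of the articular patch."""

    points_mm: np.ndarray
    plane_centroid: np.ndarray
    plane_normal: np.ndarray
    planarity_rms_mm: float

    def __post_init__(self):
        self.points_mm = np.asarray(self.points_mm, dtype=float).reshape(-1, 3)
        if len(self.points_mm) < 8:
            raise ValueError("rim loop needs at least 8 points")
        n = np.asarray(self.plane_normal, dtype=float)
        self.plane_normal = n / np.linalg.norm(n)
        self.plane_centroid = np.asarray(self.plane_centroid, dtype=float).reshape(3)


@dataclass
class MorphometryReport:
    inclination_deg: float
    anteversion_deg: float
    lce_deg: float
    extrusion_index_pct: float
    total_cov_pct: float
    anterior_cov_pct: float
    posterior_cov_pct: float
    head: HeadSphere | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("extrusion_index_pct", "total_cov_pct", "anterior_cov_pct",
                     "posterior_cov_pct"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 100]")

    def as_dict(self) -> dict:
        d = {k: float(getattr(self, k)) for k in PARAMETERS}
        if self.head is not None:
            d["head_center_mm"] = self.head.center_mm.tolist()
            d["head_radius_mm"] = float(self.head.radius_mm)
        d["flags"] = self.flags
        return d


# ---------------------------------------------------------------------------
# femoral head sphere

def _algebraic_sphere_fit(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through points: ||x||^2 = 2 c.x + (r^2 - ||c||^2)."""
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate sphere fit")
    return center, float(np.sqrt(r2))


def fit_head_sphere(femur_mesh: SurfaceMesh, init_center: np.ndarray,
                    expected_radius_mm: float = 24.0, inlier_tol_mm: float = 0.5,
                    n_ransac: int = 200, seed: int = 0) -> HeadSphere:
    """RANSAC sphere fit to the femoral head portion of the femur surface.

    Candidate vertices are those within 1.5x the expected radius of
    ``init_center`` (from the landmark stage or a centroid heuristic);
    neck/shaft vertices inside that ball are rejected as RANSAC outliers.
    Raises when fewer than 30% of candidates support a sphere.
    """
    verts = femur_mesh.vertices
    if len(verts) < 4:
        raise ValueError("femur mesh too small for a sphere fit")
    init_center = np.asarray(init_center, dtype=float).reshape(3)
    cand = verts[np.linalg.norm(verts - init_center, axis=1) <= 1.5 * expected_radius_mm]
    if len(cand) < 4:
        raise ValueError("no femur vertices near the initial head center")
    rng = np.random.default_rng(seed)
    best_inl = None
    best_count = -1
    for _ in range(n_ransac):
        idx = rng.choice(len(cand), 4, replace=False)
        try:
            c, r = _algebraic_sphere_fit(cand[idx])
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not (0.3 * expected_radius_mm <= r <= 3.0 * expected_radius_mm):
            continue
        resid = np.abs(np.linalg.norm(cand - c, axis=1) - r)
        inl = resid <= inlier_tol_mm
        if inl.sum() > best_count:
            best_count = int(inl.sum())
            best_inl = inl
    frac = best_count / len(cand) if best_count > 0 else 0.0
    if best_inl is None or frac < 0.30:
        raise ValueError(
            f"no spherical head found (inlier fraction {frac:.2f} < 0.30)"
        )
    # refine on inliers, then re-select inliers once and refit
    c, r = _algebraic_sphere_fit(cand[best_inl])
    resid = np.abs(np.linalg.norm(cand - c, axis=1) - r)
    inl = resid <= inlier_tol_mm
    if inl.sum() >= 4:
        c, r = _algebraic_sphere_fit(cand[inl])
        frac = float(inl.mean())
    return HeadSphere(center_mm=c, radius_mm=r, inlier_fraction=frac)


# ---------------------------------------------------------------------------
# articular patch and rim

def _vertex_components(n_vertices: int, faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    m = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n_vertices, n_vertices))
    _, comp = connected_components(m, directed=False)
    return comp


def extract_articular_patch(acetab_mesh: SurfaceMesh, head: HeadSphere,
                            joint_space_mm: float = 3.0, tol_mm: float = 2.0
                            ) -> SurfaceMesh:
    """Largest connected acetabular region facing the femoral head.

    Selects vertices whose distance from the head sphere surface,
    ``| ||v - c|| - r |``, is at most ``joint_space + tol`` — i.e. the
    lunate/articular surface — and keeps the largest connected component.
    """
    verts = acetab_mesh.vertices
    d = np.abs(np.linalg.norm(verts - head.center_mm, axis=1) - head.radius_mm)
    keep = d <= joint_space_mm + tol_mm
    if not keep.any():
        raise ValueError("no acetabular surface within joint-space reach of the head")
    fmask = keep[acetab_mesh.faces].all(axis=1)
    faces = acetab_mesh.faces[fmask]
    if len(faces) == 0:
        raise ValueError("articular patch has no complete triangles")
    comp = _vertex_components(len(verts), faces)
    used = np.unique(faces)
    labels, counts = np.unique(comp[used], return_counts=True)
    main = labels[np.argmax(counts)]
    faces = faces[(comp[faces[:, 0]] == main)]
    # reindex to a compact mesh
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(verts[used], remap[faces])


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    if len(boundary) == 0:
        return []
    nxt = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
    loops = []
    remaining = {(int(a), int(b)) for a, b in boundary}
    while remaining:
        start, cur = next(iter(remaining))
        loop = [start]
        edge = (start, cur)
        while edge in remaining:
            remaining.discard(edge)
            loop.append(edge[1])
            cands = [v for v in nxt.get(edge[1], []) if (edge[1], v) in remaining]
            if not cands:
                break
            edge = (edge[1], cands[0])
        if loop[0] == loop[-1]:
            loop = loop[:-1]
        loops.append(np.asarray(loop))
    return loops


def extract_rim(patch: SurfaceMesh, head: HeadSphere | None = None) -> AcetabularRim:
    """Rim = longest open boundary loop of the articular patch.

    When the head sphere is given, the boundary points are snapped
    radially onto the patch's articular radius (the median distance of
    patch vertices from the FHC), so the rim traces the articular edge
    rather than the outside of the selection band.  The opening plane is
    the least-squares plane of the loop; its normal is oriented from the
    cup interior out through the opening (lateral for a normal hip).
    """
    loops = _boundary_loops(patch.faces)
    if not loops:
        raise ValueError("articular patch is closed: no rim boundary found")

    def loop_length(loop):
        p = patch.vertices[loop]
        return np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1).sum()

    loop = max(loops, key=loop_length)
    pts = patch.vertices[loop]
    if head is not None:
        r_art = float(np.median(np.linalg.norm(patch.vertices - head.center_mm, axis=1)))
        rel = pts - head.center_mm
        pts = head.center_mm + r_art * rel / np.linalg.norm(rel, axis=1, keepdims=True)
    if len(pts) < 8:
        raise ValueError(f"rim loop too short ({len(pts)} points)")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[2]
    rms = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    # orient out of the cup: from the patch centroid through the rim plane
    if np.dot(normal, centroid - patch.vertices.mean(axis=0)) < 0:
        normal = -normal
    return AcetabularRim(points_mm=pts, plane_centroid=centroid,
                         plane_normal=normal, planarity_rms_mm=rms)


def cup_angles(rim: AcetabularRim) -> tuple[float, float]:
    """(inclination_deg, anteversion_deg) of the acetabular opening plane."""
    return geometry.cup_angles_from_axis(rim.plane_normal)


# ---------------------------------------------------------------------------
# coverage by ray casting

def _ray_mesh_any_hit(center: np.ndarray, dirs: np.ndarray, mesh: SurfaceMesh,
                      max_reach: float) -> np.ndarray:
    """Boolean per direction: ray from center hits the mesh within max_reach.

    Möller–Trumbore over candidate (ray, triangle) pairs; candidates come
    from a KD-tree over triangle-centroid directions, with an angular
    radius covering the largest triangle (faces subtending very wide
    angles are tested against every ray).
    """
    tri = mesh.vertices[mesh.faces] - center  # (M, 3, 3)
    if len(tri) == 0:
        raise ValueError("empty acetabular mesh")
    tnorm = np.linalg.norm(tri, axis=2)
    cen = tri.mean(axis=1)
    cen_n = np.linalg.norm(cen, axis=1)
    valid = cen_n > 1e-9
    u_cen = np.zeros_like(cen)
    u_cen[valid] = cen[valid] / cen_n[valid, None]
    # angular radius of each face as seen from the center
    cosang = np.einsum("mkj,mj->mk", tri / np.maximum(tnorm, 1e-12)[..., None], u_cen)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0)).max(axis=1)
    wide = (~valid) | (ang > np.deg2rad(25.0))
    narrow = np.nonzero(~wide)[0]
    from scipy.spatial import cKDTree

    pairs_r: list[np.ndarray] = []
    pairs_t: list[np.ndarray] = []
    if len(narrow):
        max_ang = ang[narrow].max()
        chord = 2.0 * np.sin(min(max_ang + 0.02, np.pi / 2) / 2.0)
        tree = cKDTree(u_cen[narrow])
        hits = tree.query_ball_point(dirs, r=chord + 1e-6)
        for i, lst in enumerate(hits):
            if lst:
                pairs_r.append(np.full(len(lst), i))
                pairs_t.append(narrow[np.asarray(lst)])
    wide_idx = np.nonzero(wide)[0]
    if len(wide_idx):
        pairs_r.append(np.repeat(np.arange(len(dirs)), len(wide_idx)))
        pairs_t.append(np.tile(wide_idx, len(dirs)))
    covered = np.zeros(len(dirs), dtype=bool)
    if not pairs_r:
        return covered
    ri = np.concatenate(pairs_r)
    ti = np.concatenate(pairs_t)
    a, b, c = tri[ti, 0], tri[ti, 1], tri[ti, 2]
    d = dirs[ri]
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, h)
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / det
        s = -a
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * np.einsum("ij,ij->i", d, q)
        t = f * np.einsum("ij,ij->i", e2, q)
    tol = 1e-9
    hit = (np.abs(det) > eps) & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) \
        & (t > 1e-9) & (t <= max_reach)
    np.logical_or.at(covered, ri[hit], True)
    return covered


def coverage(head: HeadSphere, acetab_mesh: SurfaceMesh, n_dirs: int = 10000,
             max_reach_mm: float | None = None) -> tuple[float, float, float]:
    """(total, anterior, posterior) femoral head coverage, percent.

    A direction on the head sphere is covered iff the ray from the FHC
    intersects the acetabular surface within ``max_reach`` (default
    1.5x head radius).  Anterior/posterior are covered fractions within
    the respective hemisphere of directions (split at the coronal plane
    through the FHC).
    """
    if max_reach_mm is None:
        max_reach_mm = 1.5 * head.radius_mm
    dirs = geometry.fibonacci_sphere(n_dirs)
    covered = _ray_mesh_any_hit(head.center_mm, dirs, acetab_mesh, max_reach_mm)
    total = 100.0 * covered.mean()
    ant = dirs[:, 1] > 0
    post = dirs[:, 1] < 0
    anterior = 100.0 * covered[ant].mean() if ant.any() else 0.0
    posterior = 100.0 * covered[post].mean() if post.any() else 0.0
    return float(total), float(anterior), float(posterior)


# ---------------------------------------------------------------------------
# coronal-projection parameters

def lce_angle(head: HeadSphere, rim_points_mm: np.ndarray) -> float:
    """Lateral center-edge (Wiberg) angle, degrees, coronal projection.

    Angle at the FHC between the superior direction (+z) and the ray to
    the most lateral rim point (max x), signed positive laterally.
    """
    pts = np.atleast_2d(np.asarray(rim_points_mm, dtype=float))
    edge = pts[np.argmax(pts[:, 0])]
    dx = edge[0] - head.center_mm[0]
    dz = edge[2] - head.center_mm[2]
    return float(np.degrees(np.arctan2(dx, dz)))


def extrusion_index(head: HeadSphere, rim_points_mm: np.ndarray) -> float:
    """Extrusion index, percent of head width lateral to the rim (coronal).

    EI = max(0, (c_x + r) - x_rim_lateral) / (2 r) * 100.
    """
    pts = np.atleast_2d(np.asarray(rim_points_mm, dtype=float))
    x_rim = float(np.max(pts[:, 0]))
    x_head = head.center_mm[0] + head.radius_mm
    ei = max(0.0, x_head - x_rim) / (2.0 * head.radius_mm) * 100.0
    return float(min(ei, 100.0))


# ---------------------------------------------------------------------------
# deformity classification

@dataclass
class DeformityInputs:
    alpha_deg: float
    lce_deg: float
    femoral_version_deg: float

    def __post_init__(self):
        for name in ("alpha_deg", "lce_deg", "femoral_version_deg"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def classify_deformity(inputs: DeformityInputs) -> set[str]:
    """Rule-based deformity labels.

    cam: alpha > 60 deg; pincer: LCE > 40 deg; mixed: both; DDH: LCE <
    22 deg; increased/decreased femoral version: > 25 / < 10 deg.
    Returns {"none"} when no rule fires.
    """
    labels = set()
    if inputs.alpha_deg > 60:
        labels.add("cam")
    if inputs.lce_deg > 40:
        labels.add("pincer")
    if {"cam", "pincer"} <= labels:
        labels.add("mixed")
    if inputs.lce_deg < 22:
        labels.add("DDH")
    if inputs.femoral_version_deg > 25:
        labels.add("increased_FV")
    elif inputs.femoral_version_deg < 10:
        labels.add("decreased_FV")
    return labels or {"none"}


# ---------------------------------------------------------------------------
# orchestrator

def morphometry_report(labels: LabelMap | None = None, *,
                       femur_mesh: SurfaceMesh | None = None,
                       acetab_mesh: SurfaceMesh | None = None,
                       fhc_hint_mm: np.ndarray | None = None,
                       head: HeadSphere | None = None,
                       joint_space_mm: float = 3.0,
                       expected_radius_mm: float = 24.0,
                       smooth_sigma_vox: float = 0.6,
                       n_dirs: int = 10000, seed: int = 0) -> MorphometryReport:
    """Full morphometry from a label map or from femur/acetabulum meshes.

    Pipeline: head-sphere fit -> articular patch -> rim -> opening
    angles -> ray-cast coverage -> LCE -> extrusion index.  Quality
    flags from every stage are carried in the report.
    """
    if labels is not None:
        present = set(np.unique(labels.values).tolist())
        if 1 not in present:
            raise ValueError("femur label (1) missing from label map")
        if 2 not in present:
            raise ValueError("acetabulum label (2) missing from label map")
        femur_mesh = extract_surface(labels, 1, smooth_sigma_vox)
        acetab_mesh = extract_surface(labels, 2, smooth_sigma_vox)
        if fhc_hint_mm is None:
            idx = np.argwhere(labels.values == 1)
            fhc_hint_mm = labels.index_to_world(idx).mean(axis=0)
    if femur_mesh is None or acetab_mesh is None:
        raise ValueError("provide a label map or both femur and acetabulum meshes")
    if fhc_hint_mm is None:
        fhc_hint_mm = femur_mesh.vertices.mean(axis=0)

    flags: dict = {}
    if head is None:
        head = fit_head_sphere(femur_mesh, fhc_hint_mm,
                               expected_radius_mm=expected_radius_mm, seed=seed)
    flags.update(head.flags)
    flags["head_inlier_fraction"] = head.inlier_fraction
    patch = extract_articular_patch(acetab_mesh, head, joint_space_mm=joint_space_mm)
    rim = extract_rim(patch, head)
    flags["rim_planarity_rms_mm"] = rim.planarity_rms_mm
    incl, av = cup_angles(rim)
    total, ant, post = coverage(head, acetab_mesh, n_dirs=n_dirs)
    return MorphometryReport(
        inclination_deg=incl,
        anteversion_deg=av,
        lce_deg=lce_angle(head, rim.points_mm),
        extrusion_index_pct=extrusion_index(head, rim.points_mm),
        total_cov_pct=total,
        anterior_cov_pct=ant,
        posterior_cov_pct=post,
        head=head,
        flags=flags,
    )
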