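"""Metrics vs independent oracles; surfaces, distances, ICP."""

import numpy as np
import pytest

from hip3d.evaluation import (
    MetricsReport,
    RigidTransform,
    compare_models,
    dice,
    extract_surface,
    icp_align,
    points_to_mesh_distance,
    precision_recall,
    surface_distances,
    surface_distances_edt,
)
from hip3d.geometry import rotation_matrix
from hip3d.io_formats import LabelMap, SurfaceMesh


def _lab(arr):
    return LabelMap(values=np.asarray(arr, dtype=np.uint8), spacing_mm=[1.0] * 3)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_overlap(p, r):
    """Set-arithmetic oracle: explicit voxel index sets."""
    ps = {tuple(i) for i in np.argwhere(p)}
    rs = {tuple(i) for i in np.argwhere(r)}
    inter = len(ps & rs)
    return inter, len(ps), len(rs)


def oracle_point_triangle(p, a, b, c):
    """Scalar closest-distance oracle: enumerate face/edges/vertices."""
    candidates = [a, b, c]
    # project on the supporting plane
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn > 1e-12:
        n = n / nn
        q = p - np.dot(p - a, n) * n
        # barycentric test
        m = np.column_stack([b - a, c - a])
        uv, *_ = np.linalg.lstsq(m, q - a, rcond=None)
        if uv[0] >= -1e-12 and uv[1] >= -1e-12 and uv.sum() <= 1 + 1e-12:
            candidates.append(q)
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        t = np.clip(np.dot(p - e0, d) / np.dot(d, d), 0.0, 1.0)
        candidates.append(e0 + t * d)
    return min(np.linalg.norm(p - c_) for c_ in candidates)


def oracle_surface_distances(ma, mb):
    def directed(src, dst):
        tri = dst.vertices[dst.faces]
        return np.array([min(oracle_point_triangle(p, *t) for t in tri)
                         for p in src.vertices])

    d_ab = directed(ma, mb)
    d_ba = directed(mb, ma)
    return 0.5 * (d_ab.mean() + d_ba.mean()), max(d_ab.max(), d_ba.max())


# ---------------------------------------------------------------------------
# overlap metrics

def test_dice_closed_forms():
    a = np.zeros((4, 4, 4))
    a[0, 0, :2] = 1
    b = np.zeros((4, 4, 4))
    b[0, 0, 0] = 1
    assert dice(_lab(a), _lab(a), 1) == 1.0
    assert dice(_lab(a), _lab(b), 1) == pytest.approx(2 / 3)
    assert dice(_lab(np.zeros((4, 4, 4))), _lab(np.zeros((4, 4, 4))), 1) == 1.0
    assert dice(_lab(a), _lab(np.zeros((4, 4, 4))), 1) == 0.0
    with pytest.raises(ValueError, match="mismatch"):
        dice(_lab(a), _lab(np.zeros((5, 4, 4))), 1)


def test_overlap_metrics_equal_brute_force_oracle(rng):
    for _ in range(100):
        p = rng.random((8, 8, 8)) < 0.3
        r = rng.random((8, 8, 8)) < 0.3
        inter, np_, nr = brute_force_overlap(p, r)
        d = dice(_lab(p), _lab(r), 1)
        expected = 1.0 if (np_ + nr) == 0 else 2 * inter / (np_ + nr)
        assert d == expected
        if np_ and nr:
            prec, rec = precision_recall(_lab(p), _lab(r), 1)
            assert prec == inter / np_
            assert rec == inter / nr


def test_precision_recall_contracts(rng):
    r = np.zeros((6, 6, 6))
    r[1:5, 1:5, 1:5] = 1
    p = np.zeros_like(r)
    p[2:4, 2:4, 2:4] = 1  # strict subset
    prec, rec = precision_recall(_lab(p), _lab(r), 1)
    assert prec == 1.0 and rec < 1.0
    assert precision_recall(_lab(r), _lab(r), 1) == (1.0, 1.0)
    # symmetry: precision(P,R) = recall(R,P)
    a = rng.random((6, 6, 6)) < 0.4
    assert precision_recall(_lab(a), _lab(r), 1)[0] == \
        precision_recall(_lab(r), _lab(a), 1)[1]
    with pytest.raises(ValueError, match="absent"):
        precision_recall(_lab(np.zeros((4, 4, 4))), _lab(r[:4, :4, :4]), 1)


# ---------------------------------------------------------------------------
# surfaces

def test_sphere_surface_area():
    # digital ball radius 10 voxels at 1 mm -> area within 5% of 4 pi r^2
    idx = np.indices((25, 25, 25))
    mask = ((idx - 12) ** 2).sum(axis=0) <= 10**2
    mesh = extract_surface(_lab(mask), 1, smooth_sigma_vox=0.6)
    import trimesh

    area = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).area
    assert area == pytest.approx(4 * np.pi * 10**2, rel=0.05)


def test_single_voxel_closed_mesh():
    m = np.zeros((5, 5, 5))
    m[2, 2, 2] = 1
    mesh = extract_surface(_lab(m), 1)
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    assert tm.is_watertight
    assert tm.volume > 0


def test_two_components_give_two_shells():
    m = np.zeros((9, 9, 9))
    m[1:3, 1:3, 1:3] = 1
    m[6:8, 6:8, 6:8] = 1
    mesh = extract_surface(_lab(m), 1)
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    assert len(tm.split(only_watertight=False)) == 2


def test_absent_label_rejected():
    with pytest.raises(ValueError, match="absent"):
        extract_surface(_lab(np.zeros((5, 5, 5))), 1)


# ---------------------------------------------------------------------------
# surface distances

def _patch(z, n=5):
    """Flat square triangulated patch at height z."""
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, float(z))])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    return SurfaceMesh(verts, np.asarray(faces))


def test_parallel_patches_distance():
    a, b = _patch(0.0), _patch(3.0)
    asd, hd, _ = surface_distances(a, b)
    assert asd == pytest.approx(3.0, abs=1e-9)
    assert hd >= 3.0

    asd0, hd0, _ = surface_distances(a, a)
    assert asd0 == 0.0 and hd0 == 0.0


def test_distances_equal_exhaustive_oracle(rng):
    # random small meshes vs the scalar enumeration oracle
    for _ in range(5):
        pts = rng.normal(size=(12, 3)) * 5
        import scipy.spatial

        hull_a = scipy.spatial.ConvexHull(pts)
        hull_b = scipy.spatial.ConvexHull(rng.normal(size=(12, 3)) * 5 + [2, 1, 0])
        ma = SurfaceMesh(hull_a.points, hull_a.simplices)
        mb = SurfaceMesh(hull_b.points, hull_b.simplices)
        asd, hd, _ = surface_distances(ma, mb)
        o_asd, o_hd = oracle_surface_distances(ma, mb)
        assert asd == pytest.approx(o_asd, abs=1e-9)
        assert hd == pytest.approx(o_hd, abs=1e-9)


def test_kdtree_path_matches_exhaustive(rng):
    # force the pruned KD-tree path and compare with the exhaustive path
    idx = np.indices((21, 21, 21))
    mask = ((idx - 10) ** 2).sum(axis=0) <= 8**2
    mesh = extract_surface(_lab(mask), 1)
    assert mesh.n_faces > 512  # uses the KD-tree candidates
    pts = rng.normal(size=(40, 3)) * 6 + 10
    d_fast = points_to_mesh_distance(pts, mesh)
    d_slow = points_to_mesh_distance(pts, mesh, exhaustive_below=10**9)
    assert np.allclose(d_fast, d_slow, atol=1e-9)


def test_distance_metrics_rigid_invariance(rng):
    a, b = _patch(0.0), _patch(2.0)
    r = rotation_matrix([1, 2, 3], 25.0)
    t = np.array([4.0, -2.0, 7.0])
    asd1, hd1, _ = surface_distances(a, b)
    asd2, hd2, _ = surface_distances(a.transformed(r, t), b.transformed(r, t))
    assert asd2 == pytest.approx(asd1, abs=1e-9)
    assert hd2 == pytest.approx(hd1, abs=1e-9)


def test_asd_never_exceeds_hausdorff(rng):
    for _ in range(20):
        p = rng.random((8, 8, 8)) < 0.2
        q = rng.random((8, 8, 8)) < 0.2
        if not (p.any() and q.any()):
            continue
        ma = extract_surface(_lab(p), 1)
        mb = extract_surface(_lab(q), 1)
        asd, hd, _ = surface_distances(ma, mb)
        assert asd <= hd + 1e-12


def test_edt_fallback_agrees_on_dilation(rng):
    m = np.zeros((16, 16, 16))
    m[4:12, 4:12, 4:12] = 1
    from scipy.ndimage import binary_dilation

    d = binary_dilation(m.astype(bool))
    asd, hd = surface_distances_edt(_lab(d), _lab(m), 1)
    assert asd <= np.sqrt(3.0)
    assert hd <= np.sqrt(3.0) + 1e-9


# ---------------------------------------------------------------------------
# rigid alignment

def test_metrics_report_invariants():
    with pytest.raises(ValueError):
        MetricsReport("femur", 101.0, 50.0, 50.0, 1.0, 2.0)
    with pytest.raises(ValueError):
        MetricsReport("femur", 50.0, 50.0, 50.0, 3.0, 2.0)


def test_rigid_transform_validation():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # improper
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))


def test_icp_recovers_known_transform(dysplastic_sample):
    mesh = extract_surface(dysplastic_sample.labels, 1, smooth_sigma_vox=0.6)
    r = rotation_matrix([0.3, 1.0, 0.2], 5.0)
    t = np.array([1.2, -0.8, 1.4])
    target = mesh.transformed(r, t)
    tf, rms = icp_align(mesh, target, max_iter=60)
    angle = np.degrees(np.arccos(np.clip((np.trace(tf.rotation @ r.T) - 1) / 2, -1, 1)))
    assert angle < 0.5
    assert np.linalg.norm(tf.translation - t) < 0.1
    # residual surface error after alignment is essentially zero
    assert rms < 0.01


def test_icp_identity_and_zero_iterations(dysplastic_sample):
    mesh = extract_surface(dysplastic_sample.labels, 2, smooth_sigma_vox=0.6)
    tf, rms = icp_align(mesh, mesh, max_iter=50)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-6)
    assert rms == pytest.approx(0.0, abs=1e-9)
    tf0, rms0 = icp_align(mesh, mesh.transformed(np.eye(3), [2.0, 0, 0]), max_iter=0)
    assert np.allclose(tf0.rotation, np.eye(3))
    assert np.allclose(tf0.translation, 0.0)
    # initial RMS reflects the un-aligned offset (projected onto the surface)
    assert 0.3 < rms0 <= 2.0


def test_icp_degenerate_source_rejected():
    line = SurfaceMesh(np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)]),
                       [[0, 1, 2]])
    with pytest.raises(ValueError, match="degenerate"):
        icp_align(line, line)


# ---------------------------------------------------------------------------
# bundled comparison

def test_compare_models_self_and_dilated(desk_sample):
    lab = desk_sample.labels
    self_rep = compare_models(lab, lab)
    for rep in self_rep.values():
        assert rep.doc_pct == pytest.approx(100.0)
        assert rep.asd_mm == pytest.approx(0.0, abs=1e-12)

    from scipy.ndimage import binary_dilation

    vals = lab.values.copy()
    femur_dilated = binary_dilation(vals == 1) | (vals == 1)
    vals2 = np.where(femur_dilated & (vals == 0), 1, vals).astype(np.uint8)
    pred = LabelMap(values=vals2, spacing_mm=lab.spacing_mm, origin_mm=lab.origin_mm)
    rep = compare_models(pred, lab)["femur"]
    voxel_diag = np.sqrt(3) * lab.spacing_mm[0]
    assert rep.asd_mm <= voxel_diag
    assert rep.recall_pct == pytest.approx(100.0)
    assert rep.precision_pct < 100.0
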