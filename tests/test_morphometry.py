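"""Head-sphere fit, rim extraction, coverage, LCE/EI, deformity rules."""

import numpy as np
import pytest

from hip3d import geometry
from hip3d.evaluation import extract_surface
from hip3d.io_formats import SurfaceMesh
from hip3d.morphometry import (
    AcetabularRim,
    DeformityInputs,
    HeadSphere,
    classify_deformity,
    coverage,
    cup_angles,
    extract_articular_patch,
    extract_rim,
    extrusion_index,
    fit_head_sphere,
    lce_angle,
    morphometry_report,
)


def _icosphere(radius, center, subdivisions=3):
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices) + center, np.asarray(m.faces))


class TestHeadSphere:
    def test_exact_fit_on_perfect_sphere(self):
        mesh = _icosphere(24.0, [10.0, -5.0, 3.0])
        head = fit_head_sphere(mesh, [9.0, -4.0, 2.0])
        assert np.allclose(head.center_mm, [10.0, -5.0, 3.0], atol=1e-6)
        assert head.radius_mm == pytest.approx(24.0, abs=1e-6)

    def test_phantom_femur_with_neck(self, default_sample):
        s = default_sample
        mesh = extract_surface(s.labels, 1, smooth_sigma_vox=0.6)
        head = fit_head_sphere(mesh, s.fhc_mm + [2.0, -1.0, 1.0])
        assert np.linalg.norm(head.center_mm - s.fhc_mm) < 0.3
        assert head.radius_mm == pytest.approx(s.spec.head_radius_mm, abs=0.3)
        assert head.inlier_fraction > 0.5

    def test_plane_rejected(self):
        xs, ys = np.meshgrid(np.linspace(0, 30, 12), np.linspace(0, 30, 12))
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
        faces = []
        for i in range(11):
            for j in range(11):
                a = i * 12 + j
                faces += [[a, a + 1, a + 12], [a + 1, a + 13, a + 12]]
        with pytest.raises(ValueError, match="no spherical head"):
            fit_head_sphere(SurfaceMesh(verts, np.asarray(faces)), [15.0, 15.0, 0.0])

    def test_implausible_radius_flagged(self):
        mesh = _icosphere(10.0, [0.0, 0.0, 0.0])
        head = fit_head_sphere(mesh, [0.0, 0.0, 0.0], expected_radius_mm=10.0)
        assert "radius_outside_anatomical_bounds" in head.flags


class TestPatchAndRim:
    def test_patch_area_matches_analytic_cap(self, default_sample):
        import trimesh

        s = default_sample
        head = HeadSphere(center_mm=s.fhc_mm, radius_mm=s.spec.head_radius_mm)
        cup = extract_surface(s.labels, 2, smooth_sigma_vox=0.6)
        patch = extract_articular_patch(cup, head)
        area = trimesh.Trimesh(patch.vertices, patch.faces, process=False).area
        r_in = s.spec.cup_inner_radius_mm
        theta = np.deg2rad(s.spec.cup_half_angle_deg)
        expected = 2 * np.pi * r_in**2 * (1 - np.cos(theta))
        assert area == pytest.approx(expected, rel=0.10)
        assert len(np.unique(patch.faces)) == len(patch.vertices)

    def test_patch_out_of_reach_rejected(self):
        head = HeadSphere(center_mm=[0.0, 0.0, 0.0], radius_mm=24.0)
        far = _icosphere(60.0, [0.0, 0.0, 0.0], subdivisions=2)
        with pytest.raises(ValueError, match="joint-space"):
            extract_articular_patch(far, head, joint_space_mm=3.0, tol_mm=0.0)

    def test_rim_is_analytic_circle(self, default_sample):
        s = default_sample
        head = HeadSphere(center_mm=s.fhc_mm, radius_mm=s.spec.head_radius_mm)
        cup = extract_surface(s.labels, 2, smooth_sigma_vox=0.6)
        rim = extract_rim(extract_articular_patch(cup, head), head)
        assert len(rim.points_mm) >= 8
        assert rim.planarity_rms_mm < 0.5
        radii = np.linalg.norm(rim.points_mm - s.fhc_mm, axis=1)
        r_in = s.spec.cup_inner_radius_mm
        assert np.allclose(radii, r_in, atol=1.0)
        # in-plane rim radius = R sin(theta) = R for the hemisphere
        in_plane = np.linalg.norm(
            (rim.points_mm - rim.plane_centroid)
            - np.outer((rim.points_mm - rim.plane_centroid) @ rim.plane_normal,
                       rim.plane_normal), axis=1)
        assert np.median(in_plane) == pytest.approx(r_in, abs=1.0)

    def test_closed_patch_has_no_rim(self):
        sphere = _icosphere(24.0, [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="closed"):
            extract_rim(sphere)

    def test_deficient_rim_subtends_reduced_azimuth(self):
        from hip3d.phantom import PhantomSpec, generate_phantom

        s = generate_phantom(PhantomSpec(rim_deficiency_deg=90.0))
        head = HeadSphere(center_mm=s.fhc_mm, radius_mm=s.spec.head_radius_mm)
        cup = extract_surface(s.labels, 2, smooth_sigma_vox=0.6)
        rim = extract_rim(extract_articular_patch(cup, head), head)
        n = s.spec.opening_axis
        e1, e2 = geometry.cup_basis(n)
        rel = rim.points_mm - s.fhc_mm
        az = np.degrees(np.arctan2(rel @ e2, rel @ e1))
        removed = np.abs(geometry.wrap_deg(az)) < 40.0  # sector center 0, half-width 45
        # near-rim boundary points at the meridian edges may fall inside,
        # but the bulk of the removed sector holds no rim-circle points
        at_rim_radius = np.abs(np.linalg.norm(rel, axis=1)
                               - s.spec.cup_inner_radius_mm) < 1.5
        rim_arc = at_rim_radius & (rel @ (-n) < 0.3 * s.spec.cup_inner_radius_mm)
        assert removed[rim_arc].mean() < 0.1


class TestAngles:
    def test_cup_angles_reference_directions(self):
        def rim_for(normal):
            e1, e2 = geometry.cup_basis(np.asarray(normal, dtype=float))
            phi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
            pts = 30.0 * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
            return AcetabularRim(points_mm=pts, plane_centroid=np.zeros(3),
                                 plane_normal=normal, planarity_rms_mm=0.0)

        assert cup_angles(rim_for([0, 0, -1.0])) == pytest.approx((0.0, 0.0))
        incl, av = cup_angles(rim_for([1.0, 0, 0]))
        assert incl == pytest.approx(90.0)
        assert av == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cup_angles(rim_for([0, 1.0, 0]))

    def test_phantom_angle_recovery(self, default_sample):
        s = default_sample
        rep = morphometry_report(labels=s.labels, fhc_hint_mm=s.fhc_mm)
        assert rep.inclination_deg == pytest.approx(54.0, abs=1.0)
        assert rep.anteversion_deg == pytest.approx(17.0, abs=1.0)


class TestCoverage:
    def test_concentric_hemisphere(self, rng):
        head = HeadSphere(center_mm=[0.0, 0.0, 0.0], radius_mm=24.0)
        # hemisphere opening superior: covered = inferior half
        import trimesh

        m = trimesh.creation.icosphere(subdivisions=4, radius=27.0)
        keep = np.asarray(m.vertices)[:, 2] < 1e-9
        fmask = keep[np.asarray(m.faces)].all(axis=1)
        cup = SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces)[fmask])
        total, ant, post = coverage(head, cup, n_dirs=10000)
        assert total == pytest.approx(50.0, abs=1.0)
        assert ant == pytest.approx(total, abs=1.0)
        assert post == pytest.approx(total, abs=1.0)

    def test_empty_mesh_rejected(self):
        head = HeadSphere(center_mm=[0.0, 0.0, 0.0], radius_mm=24.0)
        with pytest.raises(ValueError):
            coverage(head, SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))


class TestCoronalParameters:
    HEAD = HeadSphere(center_mm=[0.0, 0.0, 0.0], radius_mm=20.0)

    def test_lce_right_triangle(self):
        # edge 10 mm superior and 10 mm lateral of the FHC -> 45 deg
        pts = np.array([[10.0, 0.0, 10.0], [0.0, 0.0, 5.0]])
        assert lce_angle(self.HEAD, pts) == pytest.approx(45.0)

    def test_lce_edge_directly_superior(self):
        assert lce_angle(self.HEAD, np.array([[0.0, 0.0, 25.0]])) == pytest.approx(0.0)

    def test_extrusion_closed_forms(self):
        # rim lateral of the whole head -> 0 %
        assert extrusion_index(self.HEAD, np.array([[25.0, 0.0, 0.0]])) == 0.0
        # rim edge at the head center plane -> half the diameter uncovered
        assert extrusion_index(self.HEAD, np.array([[0.0, 0.0, 15.0]])) == \
            pytest.approx(50.0)

    def test_phantom_sweep_monotonicity(self):
        from hip3d.phantom import PhantomSpec, analytic_truth

        lces, eis, covs = [], [], []
        for theta in (60.0, 70.0, 80.0, 90.0):
            truth = analytic_truth(PhantomSpec(cup_half_angle_deg=theta))
            lces.append(truth.lce_deg)
            eis.append(truth.extrusion_index_pct)
            covs.append(truth.total_cov_pct)
        assert np.all(np.diff(lces) > 0)
        assert np.all(np.diff(eis) < 0)
        assert np.all(np.diff(covs) > 0)


class TestDeformityRules:
    @pytest.mark.parametrize("alpha,lce,fv,expected", [
        (84.0, 31.0, 18.0, {"cam"}),
        (65.0, 45.0, 18.0, {"cam", "pincer", "mixed"}),
        (50.0, 20.0, 30.0, {"DDH", "increased_FV"}),
        (50.0, 30.0, 5.0, {"decreased_FV"}),
        (50.0, 30.0, 18.0, {"none"}),
    ])
    def test_rule_table(self, alpha, lce, fv, expected):
        labels = classify_deformity(DeformityInputs(alpha, lce, fv))
        assert labels == expected

    def test_mixed_requires_both(self):
        for alpha, lce in [(65.0, 30.0), (50.0, 45.0)]:
            labels = classify_deformity(DeformityInputs(alpha, lce, 18.0))
            assert "mixed" not in labels

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            DeformityInputs(float("nan"), 30.0, 15.0)


class TestReport:
    def test_missing_structure_rejected(self, default_sample):
        from hip3d.io_formats import LabelMap

        femur_only = LabelMap(
            values=(default_sample.labels.values == 1).astype(np.uint8),
            spacing_mm=default_sample.labels.spacing_mm)
        with pytest.raises(ValueError, match="acetabulum label"):
            morphometry_report(labels=femur_only)

    def test_report_schema_invariants(self):
        from hip3d.phantom import PhantomSpec, make_dataset

        base = PhantomSpec(voxel_size_mm=1.6, volume_shape=(64, 64, 64))
        for s in make_dataset(5, seed=3, base=base):
            rep = morphometry_report(labels=s.labels, fhc_hint_mm=s.fhc_mm,
                                     n_dirs=4000)
            for name in ("total_cov_pct", "anterior_cov_pct", "posterior_cov_pct",
                         "extrusion_index_pct"):
                assert 0.0 <= getattr(rep, name) <= 100.0
            lo = min(rep.anterior_cov_pct, rep.posterior_cov_pct)
            hi = max(rep.anterior_cov_pct, rep.posterior_cov_pct)
            assert lo - 1e-6 <= rep.total_cov_pct <= hi + 1e-6
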