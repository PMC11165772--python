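import numpy as np
import pytest

from sinusect.core import RigidTransform, TriangleMesh
from sinusect.morphometry import (
    cut_section,
    fit_closed_bspline,
    measure_length,
    profile_sinus,
    section_dims,
)
from sinusect.synthetic import ellipsoid_mesh, superellipse_tube_mesh

from conftest import ring_contour


@pytest.fixture(scope="module")
def ellipsoid():
    """Analytic ellipsoid mesh: ML/AP/SI semi-axes (6, 20, 9) mm."""
    return ellipsoid_mesh((6.0, 20.0, 9.0))


class TestMeasureLength:
    def test_ellipsoid_diameter(self, ellipsoid):
        length, y0, y1 = measure_length(ellipsoid)
        assert np.isclose(length, 40.0, atol=1e-6)
        assert np.isclose(y0, -20.0, atol=1e-6)

    def test_synthetic_length_within_voxel(self):
        from sinusect.reconstruct import extract_isosurface
        from sinusect.synthetic import SyntheticSpec, generate_cavity

        spec = SyntheticSpec(
            n_subjects_per_sex=1,
            length_mean_mm=41.3,
            length_sd_mm=0.0,
            misorientation_sd_deg=(0.0, 0.0, 0.0),
            seed=19,
        )
        s = generate_cavity(spec, 0, "female", "left")
        mesh = extract_isosurface(s.volume)
        length, _, _ = measure_length(mesh)
        assert abs(length - 41.3) <= s.volume.spacing[1]

    def test_zero_extent_error(self):
        flat = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0, 0, 1]], [[0, 1, 2]]
        )
        with pytest.raises(ValueError, match="extent"):
            measure_length(flat)

    def test_rotation_invariance_via_reorientation(self, ellipsoid):
        from sinusect.orientation import apply_transform

        t = RigidTransform(10.0, 0.0, 0.0)
        rotated = apply_transform(ellipsoid, t)
        realigned = apply_transform(rotated, t.inverse())
        l0, _, _ = measure_length(ellipsoid)
        l1, _, _ = measure_length(realigned)
        assert abs(l1 - l0) / l0 < 0.02


class TestCutSection:
    def test_central_ellipse(self, ellipsoid):
        c = cut_section(ellipsoid, 50)
        xz = c.cutting_points[:, [0, 2]]
        # all points on the (6, 9) ellipse
        assert np.allclose(
            (xz[:, 0] / 6.0) ** 2 + (xz[:, 1] / 9.0) ** 2, 1.0, atol=1e-3
        )
        assert np.allclose(c.cutting_points[:, 1], c.plane_position)

    def test_80_percent_scaling(self, ellipsoid):
        c = cut_section(ellipsoid, 80)
        d = section_dims(fit_closed_bspline(c))
        scale = np.sqrt(1.0 - 0.6**2)  # = 0.8
        assert abs(d.width_mm - 2 * 6 * scale) < 0.05
        assert abs(d.height_mm - 2 * 9 * scale) < 0.05

    def test_endpoint_degenerate(self, ellipsoid):
        for frac in (0, 100):
            c = cut_section(ellipsoid, frac)
            assert c.degenerate
            assert len(c.cutting_points) == 1

    def test_angular_ordering(self, ellipsoid):
        c = cut_section(ellipsoid, 50)
        xz = c.cutting_points[:, [0, 2]]
        ang = np.arctan2(xz[:, 1], xz[:, 0])
        assert np.all(np.diff(ang) >= 0)  # sorted by polar angle

    def test_invalid_fraction(self, ellipsoid):
        with pytest.raises(ValueError):
            cut_section(ellipsoid, 120)

    def test_disconnected_mesh_error(self):
        a = ellipsoid_mesh((3, 3, 3), center=(0, -10, 0))
        b = ellipsoid_mesh((3, 3, 3), center=(0, 10, 0))
        combined = TriangleMesh(
            np.vstack([a.vertices, b.vertices]),
            np.vstack([a.faces, b.faces + a.n_vertices]),
        )
        with pytest.raises(ValueError, match="contiguous"):
            cut_section(combined, 50)

    def test_multi_loop_envelope_pooling(self):
        """Two side-by-side tubes: envelope spans both loops."""
        a = superellipse_tube_mesh(np.full(11, 4.0), np.full(11, 6.0), 40.0)
        shift = np.array([4.0, 0.0, 0.0])
        combined = TriangleMesh(
            np.vstack([a.vertices - shift, a.vertices + shift]),
            np.vstack([a.faces, a.faces + a.n_vertices]),
        )
        c = cut_section(combined, 50)
        assert c.n_loops == 2
        d = section_dims(fit_closed_bspline(c))
        assert abs(d.width_mm - 12.0) < 0.2  # 2*shift + tube width
        assert abs(d.height_mm - 6.0) < 0.2

    def test_largest_loop_only_flag(self):
        a = superellipse_tube_mesh(np.full(11, 4.0), np.full(11, 6.0), 40.0)
        b = superellipse_tube_mesh(np.full(11, 2.0), np.full(11, 3.0), 40.0)
        combined = TriangleMesh(
            np.vstack(
                [a.vertices - [4, 0, 0], b.vertices + [4, 0, 0]]
            ),
            np.vstack([a.faces, b.faces + a.n_vertices]),
        )
        c = cut_section(combined, 50, largest_loop_only=True)
        d = section_dims(fit_closed_bspline(c))
        assert abs(d.width_mm - 4.0) < 0.2


class TestSplineFit:
    def test_circle(self):
        t = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        c = fit_closed_bspline(
            ring_contour(np.stack([5 * np.cos(t), 5 * np.sin(t)], axis=1))
        )
        d = section_dims(c)
        assert abs(d.width_mm - 10.0) < 0.01
        assert abs(d.height_mm - 10.0) < 0.01
        assert abs(d.aspect_ratio - 1.0) < 0.002

    def test_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        c = fit_closed_bspline(
            ring_contour(np.stack([6 * np.cos(t), 9 * np.sin(t)], axis=1))
        )
        d = section_dims(c)
        assert abs(d.width_mm - 12.0) < 0.05
        assert abs(d.height_mm - 18.0) < 0.05

    def test_square_extent_preservation(self):
        # corners + edge points; interpolating cubics overshoot sharp
        # corners slightly, shrinking with sampling density
        ts = np.linspace(0, 1, 17)[:-1]
        corners = [(-5, -5), (5, -5), (5, 5), (-5, 5)]
        pts = []
        for i in range(4):
            p0, p1 = np.array(corners[i]), np.array(corners[(i + 1) % 4])
            pts.extend(p0 + t * (p1 - p0) for t in ts)
        d = section_dims(fit_closed_bspline(ring_contour(pts)))
        assert abs(d.width_mm - 10.0) < 0.15
        assert abs(d.height_mm - 10.0) < 0.15

    def test_curve_closed(self):
        t = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        c = fit_closed_bspline(
            ring_contour(np.stack([5 * np.cos(t), 3 * np.sin(t)], axis=1))
        )
        from scipy import interpolate

        p0 = interpolate.splev(0.0, c.tck)
        p1 = interpolate.splev(1.0, c.tck)
        assert np.allclose(p0, p1, atol=1e-9)

    def test_max_point_to_curve_distance(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        xz = np.stack([6 * np.cos(t), 9 * np.sin(t)], axis=1)
        c = fit_closed_bspline(ring_contour(xz))
        curve = c.curve_points(4000)[:, [0, 2]]
        dists = np.array(
            [np.linalg.norm(curve - p, axis=1).min() for p in xz]
        )
        assert dists.max() <= 0.1

    def test_too_few_points_degenerate(self):
        c = fit_closed_bspline(ring_contour([(0, 0), (1, 0), (0, 1)]))
        assert c.degenerate
        d = section_dims(c)
        assert d.width_mm == 0.0 and np.isnan(d.aspect_ratio)

    def test_smoothing_parameter(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        xz = np.stack([5 * np.cos(t), 5 * np.sin(t)], axis=1)
        noisy = xz + rng.normal(0, 0.2, xz.shape)
        rough = section_dims(fit_closed_bspline(ring_contour(noisy)))
        smooth = section_dims(
            fit_closed_bspline(ring_contour(noisy), smoothing=5.0)
        )
        assert abs(smooth.width_mm - 10.0) <= abs(rough.width_mm - 10.0) + 0.05


class TestSectionDims:
    def test_ellipse_ar(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        d = section_dims(
            fit_closed_bspline(
                ring_contour(np.stack([6 * np.cos(t), 9 * np.sin(t)], axis=1))
            )
        )
        assert abs(d.aspect_ratio - 0.667) < 0.002

    def test_tall_ellipse_ar(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        d = section_dims(
            fit_closed_bspline(
                ring_contour(np.stack([5 * np.cos(t), 9 * np.sin(t)], axis=1))
            )
        )
        assert abs(d.aspect_ratio - 0.556) < 0.002


class TestProfileSinus:
    def test_recovers_ground_truth(self, clean_sinus, clean_mesh):
        prof = profile_sinus(clean_mesh, "s", "female", "left")
        truth = clean_sinus.truth
        sp = clean_sinus.volume.spacing
        for i, m in enumerate(prof.metrics):
            if m.fraction in (0, 100):
                assert m.degenerate
                continue
            assert abs(m.width_mm - truth.width_mm[i]) <= sp[0]
            assert abs(m.height_mm - truth.height_mm[i]) <= sp[2]

    def test_constant_tube_ar(self):
        mesh = superellipse_tube_mesh(np.full(11, 10.0), np.full(11, 18.0), 40.0)
        prof = profile_sinus(mesh)
        ars = [m.aspect_ratio for m in prof.metrics[1:-1]]
        assert np.allclose(ars, 10.0 / 18.0, atol=0.01)

    def test_mirror_invariance(self, clean_mesh):
        # extents are reflection-invariant; tiny spline-knot asymmetry only
        a = profile_sinus(clean_mesh).to_frame()
        b = profile_sinus(clean_mesh.mirrored_x()).to_frame()
        assert np.allclose(a["W_mm"], b["W_mm"], atol=0.01)
        assert np.allclose(a["H_mm"], b["H_mm"], atol=0.01)

    def test_fraction_step(self, ellipsoid):
        prof = profile_sinus(ellipsoid, fraction_step=20)
        assert [m.fraction for m in prof.metrics] == [0, 20, 40, 60, 80, 100]
        with pytest.raises(ValueError):
            profile_sinus(ellipsoid, fraction_step=30)

    @pytest.mark.parametrize("s", [0.5, 2.0, 3.7])
    def test_scale_equivariance(self, s, ellipsoid):
        base = profile_sinus(ellipsoid)
        scaled_mesh = TriangleMesh(ellipsoid.vertices * s, ellipsoid.faces)
        scaled = profile_sinus(scaled_mesh)
        assert np.isclose(scaled.length_mm, base.length_mm * s, rtol=1e-9)
        for mb, ms in zip(base.metrics[1:-1], scaled.metrics[1:-1]):
            assert np.isclose(ms.width_mm, mb.width_mm * s, rtol=1e-5)
            assert np.isclose(
                ms.aspect_ratio, mb.aspect_ratio, rtol=1e-6, atol=1e-6
            )

    def test_rotation_robustness_mesh_exact(self, clean_mesh, clean_sinus):
        """Misorient the mesh, recover from landmarks, reorient, re-measure:
        metrics agree with the aligned mesh within 2%."""
        from sinusect.orientation import apply_transform, compute_reorientation

        t = RigidTransform(12.0, 2.0, -2.0)
        rotated = apply_transform(clean_mesh, t)
        lm = clean_sinus.landmarks.transformed(t)
        corrected = apply_transform(rotated, compute_reorientation(lm).inverse())
        base = profile_sinus(clean_mesh).to_frame()
        prof = profile_sinus(corrected).to_frame()
        inner = slice(1, 10)
        for col in ("W_mm", "H_mm"):
            v0 = base[col].to_numpy()[inner]
            v1 = prof[col].to_numpy()[inner]
            assert np.all(np.abs(v1 - v0) / v0 < 0.02)

    def test_rotation_robustness_volume_resampled(self, clean_sinus, clean_mesh):
        """Full volume path (nearest-neighbour resample) stays within about
        one voxel of the aligned measurement."""
        from sinusect.orientation import apply_transform, reorient
        from sinusect.reconstruct import extract_isosurface

        t = RigidTransform(12.0, 2.0, -2.0)
        rotated_vol = apply_transform(clean_sinus.volume, t)
        lm = clean_sinus.landmarks.transformed(t)
        aligned, mis = reorient(rotated_vol, lm)
        assert np.allclose(mis.angles(), t.angles(), atol=0.05)
        prof = profile_sinus(extract_isosurface(aligned)).to_frame()
        base = profile_sinus(clean_mesh).to_frame()
        inner = slice(1, 10)
        tol = 1.25 * clean_sinus.volume.spacing.max()
        for col in ("W_mm", "H_mm"):
            diff = np.abs(
                prof[col].to_numpy()[inner] - base[col].to_numpy()[inner]
            )
            assert np.all(diff <= tol)
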