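"""Gradient-coil geometry, Biot–Savart fields and calibration."""

import numpy as np
import pytest

from gradvolt import coils
from gradvolt.coils import (MU0, ArcSegment, AxisCoil, CoilError,
                            SingularityError, StraightSegment,
                            build_coil_catalog, build_coil_set,
                            calibrate_gradient_efficiency, central_gradient,
                            golay_saddle_coil, maxwell_pair, segment_b_field)


def full_loop(radius=0.35, z=0.0):
    return ArcSegment(center=(0, 0, z), radius=radius)


class TestSegmentField:
    def test_loop_center_matches_closed_form(self):
        a = 0.35
        B = segment_b_field((0, 0, 0), full_loop(a), 1.0)
        assert B[2] == pytest.approx(MU0 / (2 * a), rel=1e-9)
        assert abs(B[0]) < 1e-18 and abs(B[1]) < 1e-18

    @pytest.mark.parametrize("z", np.linspace(0.0, 0.7, 8))
    def test_on_axis_loop_formula(self, z):
        # analytic on-axis field over z in [0, 2a] to 1e-6 relative
        a = 0.35
        Bz = segment_b_field((0, 0, z), full_loop(a), 1.0)[2]
        exact = MU0 * a**2 / (2 * (a**2 + z**2) ** 1.5)
        assert Bz == pytest.approx(exact, rel=1e-6)

    def test_far_field_decays(self):
        B = segment_b_field((0, 0, 1e3), full_loop(), 1.0)
        assert np.linalg.norm(B) < 1e-15

    def test_linearity_in_current(self):
        p = (0.1, 0.05, 0.2)
        B1 = segment_b_field(p, full_loop(), 1.0)
        B2 = segment_b_field(p, full_loop(), 2.0)
        np.testing.assert_allclose(B2, 2.0 * B1, rtol=0, atol=0)

    def test_point_on_wire_raises(self):
        with pytest.raises(SingularityError):
            segment_b_field((0.35, 0, 0), full_loop(0.35), 1.0)

    def test_straight_segment_closed_form(self):
        # infinite-wire limit: long straight wire along z, field at distance d
        seg = StraightSegment(start=(0, 0, -500.0), end=(0, 0, 500.0))
        d = 0.1
        B = segment_b_field((d, 0, 0), seg, 2.0)
        assert B[1] == pytest.approx(MU0 * 2.0 / (2 * np.pi * d), rel=1e-5)


class TestSegmentValidation:
    def test_degenerate_straight_rejected(self):
        with pytest.raises(CoilError):
            StraightSegment(start=(0, 0, 0), end=(0, 0, 0))

    def test_bad_arc_rejected(self):
        with pytest.raises(CoilError):
            ArcSegment(center=(0, 0, 0), radius=-1.0)
        with pytest.raises(CoilError):
            ArcSegment(center=(0, 0, 0), radius=1.0, phi0=0.0, phi1=0.0)
        with pytest.raises(CoilError):
            ArcSegment(center=(0, 0, 0), radius=1.0, polarity=2)

    def test_low_quadrature_resolution_rejected(self):
        coil = AxisCoil("Z", (full_loop(),))
        with pytest.raises(CoilError):
            coil.vector_potential(np.zeros((1, 3)), 1.0, points_per_turn=8)


class TestVectorPotential:
    def test_vanishes_on_loop_axis(self):
        coil = AxisCoil("Z", (full_loop(),))
        pts = np.array([[0, 0, 0.0], [0, 0, 0.2], [0, 0, -0.4]])
        A = coil.vector_potential(pts, 1.0)
        assert np.abs(A).max() < 1e-12

    def test_axisymmetric_coil_has_azimuthal_potential(self, coil_set):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.05, 0.25, 30)
        phi = rng.uniform(0, 2 * np.pi, 30)
        z = rng.uniform(-0.4, 0.4, 30)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        A = coil_set.z_coil.vector_potential(pts, 1.0)
        radial = np.abs(A[:, 0] * np.cos(phi) + A[:, 1] * np.sin(phi))
        assert (radial < 1e-9 * np.linalg.norm(A, axis=1)).all()

    def test_discrete_curl_reproduces_b(self, coil_set):
        # curl A on a fine grid matches the Biot-Savart field within 1%
        coil = coil_set.x_coil
        h = 1e-3
        base = np.array([0.05, 0.08, 0.1])
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                            [0, 0, 1], [0, 0, -1]], dtype=float)
        A = {tuple(o): coil.vector_potential(base + h * o, 1.0)[0]
             for o in offsets}

        def d(comp, axis):
            plus = tuple(np.eye(3)[axis])
            minus = tuple(-np.eye(3)[axis])
            return (A[plus][comp] - A[minus][comp]) / (2 * h)

        curl = np.array([d(2, 1) - d(1, 2), d(0, 2) - d(2, 0), d(1, 0) - d(0, 1)])
        B = coil.b_field(base, 1.0)[0]
        assert np.linalg.norm(curl - B) < 0.01 * np.linalg.norm(B)


class TestCalibration:
    def test_maxwell_pair_closed_form(self):
        # dBz/dz = 3 mu0 I a^2 d / (a^2+d^2)^(5/2) for loops at ±d
        a, d = 0.325, 0.28
        pair = AxisCoil("Z", (
            ArcSegment(center=(0, 0, +d), radius=a, polarity=+1),
            ArcSegment(center=(0, 0, -d), radius=a, polarity=-1)))
        cal = calibrate_gradient_efficiency(pair)
        closed = 1.0 / (3 * MU0 * a**2 * d / (a**2 + d**2) ** 2.5)
        assert abs(cal.current_per_unit_gradient) == pytest.approx(closed,
                                                                   rel=1e-6)

    def test_idempotent(self, coil_set):
        again = calibrate_gradient_efficiency(coil_set.z_coil)
        assert again.current_per_unit_gradient == pytest.approx(
            coil_set.z_coil.current_per_unit_gradient, rel=1e-12)

    def test_bz_vanishes_at_isocenter(self, coil_set):
        coil = coil_set.z_coil
        B = coil.b_field(np.zeros((1, 3)), coil.current_per_unit_gradient)[0]
        assert abs(B[2]) < 1e-9

    def test_degenerate_winding_rejected(self):
        # co-wound pair produces a uniform field, no gradient
        pair = AxisCoil("Z", (
            ArcSegment(center=(0, 0, +0.2), radius=0.3, polarity=+1),
            ArcSegment(center=(0, 0, -0.2), radius=0.3, polarity=+1)))
        with pytest.raises(coils.CalibrationError):
            calibrate_gradient_efficiency(pair)


class TestCoilCatalog:
    def test_default_catalog(self):
        cat = build_coil_catalog()
        assert len(cat) == 5
        dims = {(s.coil_diameter, s.coil_length) for s in cat}
        assert len(dims) == 5
        for s in cat:
            assert s.coil_diameter > 0.5 and s.coil_length > 0.8

    def test_unit_gradient_after_calibration(self):
        for s in build_coil_catalog([(0.6, 1.2)]):
            for ax in "XYZ":
                coil = s.coil(ax)
                g = central_gradient(coil, coil.current_per_unit_gradient)
                assert g == pytest.approx(1.0, rel=1e-6)

    def test_catalog_size_follows_config(self):
        assert len(build_coil_catalog([(0.7, 1.5)])) == 1

    def test_duplicate_pair_rejected(self):
        with pytest.raises(CoilError):
            build_coil_catalog([(0.6, 1.2), (0.6, 1.2)])

    def test_nonphysical_dimensions_rejected(self):
        with pytest.raises(CoilError):
            build_coil_set("bad", -0.6, 1.2)
        with pytest.raises(CoilError):
            build_coil_set("bad", 0.3, 1.2)  # below whole-body bore scale

    def test_windings_on_the_former(self, coil_set):
        a = coil_set.coil_diameter / 2
        for coil in (coil_set.x_coil, coil_set.y_coil):
            for seg in coil.segments:
                if isinstance(seg, ArcSegment):
                    assert seg.radius == pytest.approx(a, abs=1e-3)
                else:
                    for p in (seg.start, seg.end):
                        assert np.hypot(p[0], p[1]) == pytest.approx(a,
                                                                     abs=1e-3)


class TestSymmetry:
    def test_x_and_y_coils_related_by_rotation(self, coil_set):
        # B_y(R p) = R B_x(p) for the 90° rotation R about the bore axis
        rng = np.random.default_rng(11)
        pts = rng.uniform(-0.2, 0.2, size=(20, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        Bx = coil_set.x_coil.b_field(pts, 1.0)
        By = coil_set.y_coil.b_field(pts @ rot.T, 1.0)
        np.testing.assert_allclose(By, Bx @ rot.T, atol=1e-9)

    def test_superposition_over_segments(self, coil_set):
        p = (0.05, -0.1, 0.15)
        total = coil_set.z_coil.b_field(np.array([p]), 1.0)[0]
        by_parts = sum(segment_b_field(p, seg, 1.0)
                       for seg in coil_set.z_coil.segments)
        np.testing.assert_allclose(total, by_parts, rtol=1e-9, atol=1e-15)

    def test_transverse_gradient_is_pure(self):
        coil = calibrate_gradient_efficiency(golay_saddle_coil(0.66, 1.4, "X"))
        I = coil.current_per_unit_gradient
        h = 1e-3
        pts = np.array([[0, 0, 0], [0, h, 0], [0, 0, h]])
        Bz = coil.b_field(pts, I)[:, 2]
        assert abs(Bz[0]) < 1e-9          # no field at isocenter
        assert abs(Bz[1]) / h < 1e-3      # no dBz/dy
        assert abs(Bz[2]) / h < 1e-3      # no dBz/dz
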