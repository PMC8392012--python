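"""Filament field kernels, discretization, and map/scan superposition."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import stimcoil as sc
from stimcoil import biot_savart as bs
from stimcoil.errors import SingularityError

MU0 = 4e-7 * math.pi


def loop_field_quadrature(radius, current, rho, z):
    """Independent oracle: adaptive quadrature of the Biot-Savart integral
    for a circular loop (B_rho, B_z at cylindrical (rho, z))."""
    def integrand_z(phi):
        d2 = radius ** 2 + rho ** 2 + z ** 2 - 2 * radius * rho * math.cos(phi)
        return radius * (radius - rho * math.cos(phi)) / d2 ** 1.5

    def integrand_r(phi):
        d2 = radius ** 2 + rho ** 2 + z ** 2 - 2 * radius * rho * math.cos(phi)
        return radius * z * math.cos(phi) / d2 ** 1.5

    kz, _ = quad(integrand_z, 0, 2 * math.pi, epsabs=1e-14, epsrel=1e-12)
    kr, _ = quad(integrand_r, 0, 2 * math.pi, epsabs=1e-14, epsrel=1e-12)
    pref = MU0 * current / (4 * math.pi)
    return pref * kr, pref * kz


def square_axis_closed_form(side, current, z):
    """On-axis field of a square loop (full side a)."""
    a = side
    return (MU0 * current * a ** 2
            / (2 * math.pi * (z ** 2 + a ** 2 / 4)
               * math.sqrt(z ** 2 + a ** 2 / 2)))


class TestCircularLoop:
    def test_centre_closed_form(self):
        B = sc.circular_loop_field(0.0325, 1.0, np.zeros(3))
        assert B[2] == pytest.approx(MU0 / (2 * 0.0325), rel=1e-12)
        assert B[0] == B[1] == 0.0

    @pytest.mark.parametrize("rho, z", [(10e-3, 5e-3), (25e-3, -8e-3),
                                        (40e-3, 0.5e-3)])
    def test_off_axis_matches_quadrature_oracle(self, rho, z):
        a, I = 32.5e-3, 1.0
        B = sc.circular_loop_field(a, I, np.array([rho, 0.0, z]))
        br_ref, bz_ref = loop_field_quadrature(a, I, rho, z)
        assert B[0] == pytest.approx(br_ref, rel=1e-9, abs=1e-18)
        assert B[2] == pytest.approx(bz_ref, rel=1e-9)

    def test_evaluation_on_filament_is_singular(self):
        with pytest.raises(SingularityError):
            sc.circular_loop_field(0.03, 1.0, np.array([0.03, 0.0, 0.0]))


class TestSquareLoop:
    def test_centre_closed_form(self):
        a = 0.150
        B = sc.square_loop_field(a, 1.0, np.zeros(3))
        assert B[2] == pytest.approx(2 * math.sqrt(2) * MU0 / (math.pi * a),
                                     rel=1e-12)

    @pytest.mark.parametrize("z", [1e-3, 10e-3, 61.585e-3, 0.2])
    def test_on_axis_matches_closed_form(self, z):
        a = 0.150
        B = sc.square_loop_field(a, 1.0, np.array([0.0, 0.0, z]))
        assert B[2] == pytest.approx(square_axis_closed_form(a, 1.0, z),
                                     rel=1e-12)
        assert abs(B[0]) < 1e-18 and abs(B[1]) < 1e-18

    def test_opposite_currents_cancel_exactly(self):
        pts = np.array([[0.01, 0.02, 0.03], [-0.05, 0.0, 0.1], [0.2, 0.1, -0.04]])
        for p in pts:
            total = (sc.square_loop_field(0.15, 2.5, p)
                     + sc.square_loop_field(0.15, -2.5, p))
            assert np.all(total == 0.0)

    def test_on_segment_evaluation_is_singular(self):
        with pytest.raises(SingularityError):
            sc.square_loop_field(0.15, 1.0, np.array([0.075, 0.0, 0.0]))


class TestDiscretize:
    def test_ampere_turns_conserved_exactly(self, air_coil):
        for nr, nz in [(1, 1), (3, 5), (12, 12)]:
            fils = sc.discretize(air_coil, 15.0, nr, nz)
            total = sum(f.current for f in fils)
            assert total == pytest.approx(air_coil.turns * 15.0, rel=1e-12)

    def test_single_subdivision_is_centroid_filament(self, air_coil):
        (f,) = sc.discretize(air_coil, 1.0, 1, 1)
        assert f.characteristic_size == pytest.approx(air_coil.mean_radius)
        assert f.axial_position == pytest.approx(air_coil.axial_center)

    def test_centre_field_converged_at_default_resolution(self, air_coil, drive15):
        vals = []
        for n in (8, 16):
            fils = sc.discretize(air_coil, 15.0, n, n)
            B, _ = bs.evaluate_filaments(fils, np.zeros((1, 3)))
            vals.append(np.linalg.norm(B))
        assert abs(vals[1] - vals[0]) / vals[1] < 0.005


class TestFieldMapsAndScans:
    def test_air_core_exceeds_50_mT_in_target_region(self, air_coil, drive15):
        scan = sc.line_scan(air_coil, drive15, (0, 0, 0), (0, 0, 1),
                            np.array([0.0, 2e-3, 5e-3]))
        assert np.all(scan.magnitude > 0.050)

    def test_merritt_centre_matches_plain_filament_sum(self, merritt, drive15):
        # oracle: direct loop-by-loop summation without the map machinery
        fmap = sc.field_map(merritt, "XY", (0.02, 0.02), 5e-3, drive15)
        i, j = fmap.nearest_index((0, 0, 0))
        ref = 0.0
        n = 12
        for coil in merritt.coils:
            dz = (np.arange(n) + 0.5) / n * coil.height - coil.height / 2
            half = (np.arange(n) + 0.5) / n * (coil.outer_side - coil.inner_side) / 2 \
                + coil.inner_side / 2
            for s in 2 * half:
                for z0 in dz + coil.axial_center:
                    ref += square_axis_closed_form(
                        s, 15.0 * coil.turns / n ** 2, -z0)
        assert fmap.magnitude[i, j] == pytest.approx(ref, rel=0.01)

    def test_linearity_in_current(self, air_coil):
        m1 = sc.field_map(air_coil, "XZ", (0.04, 0.04), 4e-3,
                          sc.DriveCondition(1.0), subdivisions=6)
        m15 = sc.field_map(air_coil, "XZ", (0.04, 0.04), 4e-3,
                           sc.DriveCondition(15.0), subdivisions=6)
        assert np.allclose(15 * m1.values, m15.values, rtol=1e-12, atol=1e-15)

    def test_mirror_symmetry_about_centre_plane(self, air_coil, drive15):
        z = np.array([5e-3, 12e-3, 30e-3])
        up = sc.line_scan(air_coil, drive15, (6e-3, 0, 0), (0, 0, 1), z)
        dn = sc.line_scan(air_coil, drive15, (6e-3, 0, 0), (0, 0, -1), z)
        assert np.allclose(up.magnitude, dn.magnitude, rtol=1e-12)

    def test_merritt_superposition_of_three_coils(self, merritt, drive15):
        total = sc.field_map(merritt, "XZ", (0.03, 0.03), 5e-3, drive15,
                             subdivisions=6)
        parts = sum(
            sc.field_map(coil, "XZ", (0.03, 0.03), 5e-3, drive15,
                         subdivisions=6).values
            for coil in merritt.coils)
        assert np.allclose(total.values, parts, rtol=1e-12, atol=1e-15)

    def test_singular_grid_points_masked_not_fatal(self, air_coil, drive15):
        fils = [bs.FilamentLoop("circle", 0.02, 0.0, 1.0)]
        fmap = bs.field_map_from_filaments(fils, "XZ", (0.08, 0.02), 0.01,
                                           drive15)
        assert fmap.mask is not None and fmap.mask.any()
        assert np.isnan(fmap.values[fmap.mask]).all()

    def test_divergence_vanishes_with_grid_refinement(self, air_coil, drive15):
        # central-difference div B on a small 3-D stencil cloud
        fils = sc.device_filaments(air_coil, drive15, 6, 6)
        center = np.array([8e-3, 3e-3, 6e-3])

        def div_estimate(h):
            offsets = np.array([[h, 0, 0], [-h, 0, 0], [0, h, 0],
                                [0, -h, 0], [0, 0, h], [0, 0, -h]])
            B, _ = bs.evaluate_filaments(fils, center + offsets)
            return abs((B[0, 0] - B[1, 0]) + (B[2, 1] - B[3, 1])
                       + (B[4, 2] - B[5, 2])) / (2 * h)

        scale = np.linalg.norm(
            bs.evaluate_filaments(fils, center[None, :])[0]) / 0.01
        d1, d2 = div_estimate(2e-3), div_estimate(1e-3)
        assert d2 < d1
        # second-order truncation: (h/L)^2 with L ~ 2 cm field scale
        assert d2 < 5e-3 * scale
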