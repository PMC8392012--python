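"""Map alignment, current scaling, uniformity profiles, and summaries."""

import math
from dataclasses import replace

import numpy as np
import pytest

import stimcoil as sc
from stimcoil import metrics, rig
from stimcoil.errors import (DegenerateCorrelationError, GridMismatchError,
                             ReportError, ScalingError)
from stimcoil.fieldmaps import ScanRecord


@pytest.fixture(scope="module")
def truth_map(air_coil):
    return sc.field_map(air_coil, "XZ", (0.03, 0.03), 1e-3,
                        sc.DriveCondition(1.0), subdivisions=6)


class TestAlign:
    def test_identical_maps_align_at_zero(self, truth_map):
        assert metrics.align(truth_map, truth_map) == (0, 0)

    def test_recovers_known_shift_under_noise(self, truth_map):
        sigma = 0.02 * float(np.nanmax(truth_map.magnitude))
        sensor = rig.SensorModel(noise_sigma=sigma, offset=(0, 0, 0),
                                 n_averages=1)
        rec = rig.generate_scan(truth_map, sensor, misalignment=(3, -2),
                                seed=7)
        assert metrics.align(truth_map, rec.payload) == (3, -2)

    def test_shift_equivariance(self, truth_map):
        rec = rig.generate_scan(truth_map,
                                rig.SensorModel(noise_sigma=0.0,
                                                offset=(0, 0, 0)),
                                misalignment=(2, 1), seed=0)
        fwd = metrics.align(truth_map, rec.payload)
        rev = metrics.align(rec.payload, truth_map)
        assert fwd == (2, 1)
        assert rev == (-fwd[0], -fwd[1])

    def test_constant_map_is_degenerate(self, truth_map):
        flat = replace(truth_map, values=np.zeros_like(truth_map.values))
        with pytest.raises(DegenerateCorrelationError):
            metrics.align(truth_map, flat)

    def test_step_mismatch_rejected(self, truth_map, air_coil):
        other = sc.field_map(air_coil, "XZ", (0.03, 0.03), 2e-3,
                             sc.DriveCondition(1.0), subdivisions=4)
        with pytest.raises(GridMismatchError):
            metrics.align(truth_map, other)


class TestScaleToCurrent:
    def _record(self, fmap):
        return ScanRecord(payload=fmap, condition="active",
                          current=fmap.excitation.current)

    def test_1A_to_15A_multiplies_by_15_exactly(self, truth_map):
        rec = self._record(truth_map)
        scaled = metrics.scale_to_current(rec, 15.0)
        assert np.array_equal(scaled.payload.values, truth_map.values * 15.0)
        assert scaled.current == 15.0

    def test_identity_and_round_trip(self, truth_map):
        rec = self._record(truth_map)
        same = metrics.scale_to_current(rec, 1.0)
        assert np.array_equal(same.payload.values, truth_map.values)
        back = metrics.scale_to_current(metrics.scale_to_current(rec, 15.0), 1.0)
        assert np.allclose(back.payload.values, truth_map.values, rtol=1e-15)

    def test_zero_current_scan_rejected(self, truth_map):
        rec = ScanRecord(payload=replace(truth_map,
                                         excitation=sc.DriveCondition(0.0)),
                         condition="sham", current=0.0)
        with pytest.raises(ScalingError):
            metrics.scale_to_current(rec, 15.0)


class TestUniformityProfile:
    def _line(self, positions, magnitude):
        return sc.LineScan(start=(0, 0, 0), direction=(0, 0, 1),
                           positions=positions, magnitude=magnitude,
                           excitation=sc.DriveCondition(1.0))

    def test_flat_scan_is_perfectly_uniform(self):
        pos = np.linspace(-0.05, 0.05, 101)
        profile = metrics.uniformity_profile(
            self._line(pos, np.full(101, 2e-3)), [0.01, 0.04])
        assert profile == [0.0, 0.0]

    def test_single_loop_matches_axial_falloff(self):
        # on-axis falloff of one loop: B(z)/B(0) = (a^2/(a^2+z^2))^{3/2}
        a = 0.0325
        pos = np.linspace(-0.05, 0.05, 201)
        mag = (a ** 2 / (a ** 2 + pos ** 2)) ** 1.5
        (dev,) = metrics.uniformity_profile(self._line(pos, mag), [0.02])
        expected = 100 * ((a ** 2 / (a ** 2 + 0.02 ** 2)) ** 1.5 - 1)
        assert dev == pytest.approx(expected, rel=1e-6)

    def test_scale_invariance(self):
        pos = np.linspace(-0.05, 0.05, 101)
        mag = 1e-3 * (1 + 10 * pos ** 2)
        line = self._line(pos, mag)
        scaled = self._line(pos, 1000 * mag)
        assert metrics.uniformity_profile(line, [0.03]) == \
            pytest.approx(metrics.uniformity_profile(scaled, [0.03]))

    def test_three_coil_uniformity_within_6pc_at_40mm(self, merritt, drive15):
        pos = np.arange(-0.045, 0.0455, 1e-3)
        scan = sc.line_scan(merritt, drive15, (0, 0, 0), (1, 0, 0), pos)
        (dev,) = metrics.uniformity_profile(scan, [0.04])
        assert abs(dev) < 6.0

    def test_offset_outside_scan_rejected(self):
        pos = np.linspace(-0.01, 0.01, 21)
        line = self._line(pos, np.full(21, 1e-3))
        with pytest.raises(ValueError):
            metrics.uniformity_profile(line, [0.02])


class TestSummarize:
    def _noiseless_set(self, air_coil):
        sensor = rig.SensorModel(noise_sigma=0.0, offset=(0, 0, 0))
        return rig.generate_condition_set(air_coil, sensor, seed=1,
                                          extent=(0.03, 0.03), step=1.5e-3,
                                          subdivisions=6)

    def test_noiseless_fixture_reproduces_truth_exactly(self, air_coil):
        records = self._noiseless_set(air_coil)
        truth = sc.field_map(air_coil, "XZ", (0.03, 0.03), 1.5e-3,
                             sc.DriveCondition(1.0), subdivisions=6)
        loc = (0.0, 0.0, 0.010)
        report = metrics.summarize(list(records.values()), truth, loc)
        assert report.values["active"] == pytest.approx(truth.value_at(loc),
                                                        rel=1e-12)
        assert report.relative_difference == pytest.approx(0.0, abs=1e-12)
        assert report.projected_15A == pytest.approx(
            15 * truth.value_at(loc), rel=1e-12)

    def test_attenuation_consistent_with_direct_ratio(self, air_coil):
        records = self._noiseless_set(air_coil)
        truth = sc.field_map(air_coil, "XZ", (0.03, 0.03), 1.5e-3,
                             sc.DriveCondition(1.0), subdivisions=6)
        loc = (0.0, 0.0, 0.010)
        report = metrics.summarize(list(records.values()), truth, loc)
        direct = sc.attenuation_ratio(records["active"].payload,
                                      records["sham"].payload, loc)
        assert report.attenuation == pytest.approx(direct, rel=1e-12)

    def test_control_record_is_silent_without_noise(self, air_coil):
        records = self._noiseless_set(air_coil)
        truth = sc.field_map(air_coil, "XZ", (0.03, 0.03), 1.5e-3,
                             sc.DriveCondition(1.0), subdivisions=6)
        report = metrics.summarize(list(records.values()), truth,
                                   (0.0, 0.0, 0.010))
        assert report.values["control"] == 0.0

    def test_missing_active_record_rejected(self, air_coil):
        records = self._noiseless_set(air_coil)
        truth = sc.field_map(air_coil, "XZ", (0.03, 0.03), 1.5e-3,
                             sc.DriveCondition(1.0), subdivisions=6)
        with pytest.raises(ReportError):
            metrics.summarize([records["sham"]], truth, (0, 0, 0.01))
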