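import numpy as np
import pytest

from mrsimqa import synthetic as syn
from mrsimqa.core import wrap_phase


class TestGridPhantom:
    def test_zero_model_identity(self):
        lat = syn.LatticeSpec(extent=120.0, voxel_size=2.0,
                              fov_semi_axes=(70.0, 70.0, 70.0))
        ref, meas, truth = syn.gen_grid_phantom_pair(lat, syn.DistortionModel())
        np.testing.assert_array_equal(ref.data, meas.data)
        np.testing.assert_array_equal(truth.displacement, 0.0)
        assert not truth.ambiguous

    @pytest.mark.parametrize("point", [
        (150.0, 0.0, 0.0),
        (90.0, 90.0, np.sqrt(150.0**2 - 2 * 90.0**2)),
    ])
    def test_cubic_model_magnitude_at_target_radius(self, cubic_model, point):
        # closed form: |d| = 2 mm at any point 150 mm from the isocenter
        d = cubic_model.displacement(np.array(point))
        assert np.linalg.norm(d) == pytest.approx(2.0, abs=1e-9)

    def test_default_marker_count_near_2500(self):
        pts, idx = syn.LatticeSpec().centroids()
        assert abs(len(pts) - 2500) <= 250
        # lattice indices are unique
        assert len(np.unique(idx, axis=0)) == len(idx)

    def test_large_displacement_flags_ambiguity(self):
        lat = syn.LatticeSpec(extent=120.0, voxel_size=2.0,
                              fov_semi_axes=(70.0, 70.0, 70.0))
        strong = syn.DistortionModel.cubic(15.0, 60.0)
        _, _, truth = syn.gen_grid_phantom_pair(lat, strong)
        assert truth.ambiguous

    def test_truth_csv_round_trip(self, tmp_path):
        import pandas as pd
        lat = syn.LatticeSpec(extent=120.0, voxel_size=2.0,
                              fov_semi_axes=(70.0, 70.0, 70.0))
        _, _, truth = syn.gen_grid_phantom_pair(lat, syn.DistortionModel())
        truth.to_csv(tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        assert list(df.columns) == ["i", "j", "k", "x_ref", "y_ref", "z_ref",
                                    "dx", "dy", "dz"]
        assert len(df) == len(truth.reference)


class TestPhasePair:
    def test_zero_field_constant_phase(self):
        zero = lambda x, y, z: np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape))
        p1, p2, truth = syn.gen_phase_pair(zero, phi0=0.3, voxel_size=10.0)
        mask = truth.meta["mask"]
        np.testing.assert_allclose(p1.data[mask], 0.3, atol=1e-12)
        np.testing.assert_allclose(p2.data[mask], 0.3, atol=1e-12)
        np.testing.assert_array_equal(truth.data, 0.0)

    def test_wrapped_phase_difference_closed_form(self):
        # 2 ppm peak, TE 10/12 ms, f0 = 42,587,276 Hz
        field = syn.ParabolicPPMField.from_peak(2.0, radius=155.0)
        p1, p2, truth = syn.gen_phase_pair(field, te1_ms=10.0, te2_ms=12.0,
                                           phi0=0.0, voxel_size=5.0)
        mask = truth.meta["mask"]
        expected = wrap_phase(2 * np.pi * 42_587_276.0 * 2e-6 * 0.002)
        peak_voxels = np.isclose(truth.data, truth.data[mask].max())
        dphi = wrap_phase(p2.data - p1.data)
        np.testing.assert_allclose(dphi[peak_voxels & mask],
                                   expected, atol=2e-2)

    def test_deterministic_under_seed(self):
        field = syn.ParabolicPPMField.from_peak(1.0)
        a = syn.gen_phase_pair(field, noise_sd=0.05, seed=7, voxel_size=10.0)
        b = syn.gen_phase_pair(field, noise_sd=0.05, seed=7, voxel_size=10.0)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_itoh_violation_raises(self):
        steep = syn.ParabolicPPMField.from_peak(500.0, radius=155.0)
        with pytest.raises(ValueError, match="Itoh"):
            syn.gen_phase_pair(steep, voxel_size=10.0)

    def test_te_order_enforced(self):
        field = syn.ParabolicPPMField.from_peak(1.0)
        with pytest.raises(ValueError):
            syn.gen_phase_pair(field, te1_ms=12.0, te2_ms=10.0)


class TestRampVolume:
    @pytest.mark.parametrize("thickness,angle,expected", [
        (5.0, 11.0, 5.0 / np.tan(np.radians(11.0))),   # ~25.72 mm
        (7.0, 44.999, 7.0 / np.tan(np.radians(44.999))),
        (1.0, 11.0, 1.0 / np.tan(np.radians(11.0))),
    ])
    def test_profile_width_trigonometry(self, thickness, angle, expected):
        _, width = syn.gen_ramp_volume(thickness, angle)
        assert width == pytest.approx(expected, rel=1e-12)

    def test_band_wider_than_image_raises(self):
        with pytest.raises(ValueError, match="wider"):
            syn.gen_ramp_volume(20.0, 5.0, fov=100.0)

    def test_angle_bounds(self):
        with pytest.raises(ValueError):
            syn.gen_ramp_volume(5.0, 46.0)


class TestMultiechoPhantom:
    def test_pure_water_short_te(self, multiecho_phantom):
        pairs, truth = multiecho_phantom
        mag, pha = pairs[0]  # TE = 0.144 ms << water T2*
        water = truth["masks"]["water"]
        np.testing.assert_allclose(mag.data[water], 1.0, atol=0.01)
        np.testing.assert_allclose(pha.data[water], 0.0, atol=1e-6)

    def test_bone_to_water_ratio_follows_t2star(self, multiecho_phantom):
        pairs, truth = multiecho_phantom
        mag = pairs[1][0]  # TE = 2.44 ms
        spec = truth["spec"]
        bone = truth["masks"]["bone"]
        water = truth["masks"]["water"]
        measured = mag.data[bone].mean() / mag.data[water].mean()
        expected = (spec.density["bone"] * np.exp(-2.44 / spec.t2star_ms["bone"])
                    / (spec.density["water"] * np.exp(-2.44 / spec.t2star_ms["water"])))
        assert measured == pytest.approx(expected, rel=1e-6)

    def test_fat_out_of_phase_condition(self):
        spec = syn.TissuePhantomSpec()
        te_op = 0.5 / spec.fat_water_offset_hz * 1e3  # 2 pi df TE = pi
        pairs, truth = syn.gen_multiecho_phantom(spec, tes_ms=[te_op])
        fat = truth["masks"]["fat"]
        phases = pairs[0][1].data[fat]
        np.testing.assert_allclose(np.abs(phases), np.pi, atol=1e-9)

    def test_unsorted_tes_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_multiecho_phantom(tes_ms=[2.44, 0.144])


class TestWaveform:
    def test_whole_number_of_cycles(self):
        w = syn.gen_waveform(period=3.0, duration=30.0)
        # 10 full cycles: endpoints both at phase zero
        assert w.a[0] == pytest.approx(0.0, abs=1e-9)
        assert w.a[-1] == pytest.approx(0.0, abs=1e-9)
        tol = 1e-9  # endpoint sits at phase zero only to round-off
        upcross = np.sum((w.a[:-1] < -tol) & (w.a[1:] >= -tol))
        assert upcross == 10

    def test_peak_to_peak_exact(self):
        w = syn.gen_waveform(period=4.0, peak_to_peak=3.0, duration=40.0,
                             dt=0.01)
        assert w.a.max() - w.a.min() == pytest.approx(3.0, abs=1e-4)

    def test_zero_crossing_ratio_between_periods(self):
        w3 = syn.gen_waveform(period=3.0, duration=90.0)
        w5 = syn.gen_waveform(period=5.0, duration=90.0)
        cross = lambda w: int(np.sum(np.diff(np.signbit(w.a)) != 0))
        assert cross(w3) / cross(w5) == pytest.approx(5.0 / 3.0, rel=0.05)

    def test_undersampled_dt_raises(self):
        with pytest.raises(ValueError, match="undersample"):
            syn.gen_waveform(period=3.0, dt=0.1)

    def test_short_duration_raises(self):
        with pytest.raises(ValueError, match="2 cycles"):
            syn.gen_waveform(period=5.0, duration=8.0)

    def test_drift_anomaly_applied(self):
        w = syn.gen_waveform(period=3.0, duration=30.0,
                             anomaly={"drift": 0.05})
        assert np.mean(w.a[len(w.a)//2:]) > np.mean(w.a[:len(w.a)//2])


class TestMotionSampler:
    def test_zero_amplitude_frames_identical(self):
        w = syn.gen_waveform(period=3.0, peak_to_peak=2.0, duration=30.0)
        w.a[:] = 0.0
        sam = syn.gen_motion_series(w)
        np.testing.assert_array_equal(sam.frame(5.0).data, sam.frame(20.0).data)

    def test_position_range_equals_excursion(self):
        w = syn.gen_waveform(period=3.0, duration=30.0)
        sam = syn.gen_motion_series(w, excursion=20.0)
        pos = np.array([sam.position(t) for t in np.arange(0, 30, 0.05)])
        assert pos.max() - pos.min() == pytest.approx(20.0, abs=0.01)

    def test_transmission_loss_reduces_realized_range(self):
        # programmed 30 mm excursion through a lossy string/trolley drive
        w = syn.gen_waveform(period=3.0, duration=30.0)
        sam = syn.gen_motion_series(w, excursion=30.0 * 0.6)
        pos = np.array([sam.position(t) for t in np.arange(0, 30, 0.05)])
        realized = pos.max() - pos.min()
        assert realized == pytest.approx(18.0, abs=0.01)
        assert 15.0 <= realized <= 20.0  # the reported realized band

    def test_object_must_fit_fov(self):
        w = syn.gen_waveform(period=3.0, duration=30.0)
        with pytest.raises(ValueError, match="fit"):
            syn.MotionSampler(w, object_size=190.0, excursion=20.0)
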