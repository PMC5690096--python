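import numpy as np
import pandas as pd
import pytest

from mrsimqa import fourd, synthetic as syn
from mrsimqa.core import ImageVolume


def _small_setup(period=3.0, n_phases=4, n_slices=4, duration=None):
    duration = duration or (2 * period + (n_slices * n_phases + 4) * period)
    w = syn.gen_waveform(period=period, duration=duration, dt=0.02)
    sampler = syn.gen_motion_series(
        w, object_size=40.0, excursion=20.0,
        fov=(80.0, 40.0, 120.0), spacing=(4.0, 10.0, 2.0))
    return w, sampler


class TestCalibration:
    def test_two_phase_levels_at_half_amplitude(self, breathing_3s):
        scheme = fourd.calibrate_trigger_levels(breathing_3s, 2)
        np.testing.assert_allclose(sorted(scheme.levels), [-0.5, 0.5],
                                   atol=1e-3)
        # falling (exhale limb) and rising (inhale limb) each used once
        assert sorted(scheme.slopes) == [-1, 1]

    def test_ten_levels_evenly_spaced_and_symmetric(self, breathing_3s):
        scheme = fourd.calibrate_trigger_levels(breathing_3s, 10)
        levels = np.sort(scheme.levels)
        np.testing.assert_allclose(np.diff(levels), 0.2, atol=1e-3)
        np.testing.assert_allclose(levels + levels[::-1], 0.0, atol=1e-3)
        assert scheme.n_phases == 10

    def test_flat_waveform_raises(self):
        w = syn.gen_waveform(period=3.0, duration=30.0)
        w.a[:] = 1.0
        with pytest.raises(ValueError, match="flat"):
            fourd.calibrate_trigger_levels(w, 4)

    def test_calibration_spike_reflected_and_flagged(self):
        # spike riding the first inhale peak of the calibration window
        w = syn.gen_waveform(period=3.0, duration=60.0,
                             anomaly={"spike": {"time": 0.75, "amplitude": 1.0}})
        scheme = fourd.calibrate_trigger_levels(w, 4)
        assert scheme.calibration_max > 1.01  # spike enters the window max
        assert scheme.meta["calibration_anomaly"]

    def test_phase_zero_is_end_inhale(self, breathing_3s):
        scheme = fourd.calibrate_trigger_levels(breathing_3s, 10)
        assert scheme.levels[0] == scheme.levels.max()
        assert scheme.slopes[0] == -1  # just past the inhale peak
        assert scheme.phase_labels()[0] == "0%"


class TestSimulation:
    def test_completion_every_pair_once_and_disjoint(self):
        w, sampler = _small_setup()
        scheme = fourd.calibrate_trigger_levels(w, 4)
        timeline, vols = fourd.simulate_triggered_acquisition(
            sampler, w, scheme, n_slices=4, tr_ms=2000.0)
        ev = timeline.events
        assert timeline.complete
        pairs = set(zip(ev["slice"], ev["phase"]))
        assert len(pairs) == 16 and len(ev) == 16
        # acquisition windows do not overlap
        starts = ev.t_s.values
        assert np.all(np.diff(starts) >= ev.window_s.values[:-1] - 1e-9)

    def test_epsilon_amplitude_phases_identical_to_static(self):
        w, _ = _small_setup()
        w.a *= 1e-6
        sampler = syn.gen_motion_series(
            w, object_size=40.0, excursion=20.0,
            fov=(80.0, 40.0, 120.0), spacing=(4.0, 10.0, 2.0))
        scheme = fourd.calibrate_trigger_levels(w, 2)
        _, vols = fourd.simulate_triggered_acquisition(
            sampler, w, scheme, n_slices=4, tr_ms=2000.0)
        static = sampler.frame(0.0)
        for v in vols.volumes:
            # acquired slices identical to the static frame, up to
            # sub-micrometre anti-aliasing at object edges
            np.testing.assert_allclose(v.data[:, :4, :],
                                       static.data[:, :4, :], atol=0.01)

    def test_waveform_exhaustion_raises_with_partial(self):
        w, sampler = _small_setup(duration=20.0)
        scheme = fourd.calibrate_trigger_levels(w, 4)
        with pytest.raises(fourd.AcquisitionIncompleteError) as exc:
            fourd.simulate_triggered_acquisition(sampler, w, scheme,
                                                 n_slices=4, tr_ms=2000.0)
        assert not exc.value.timeline.complete
        assert len(exc.value.timeline.events) > 0

    def test_reproducible_timelines(self):
        runs = []
        for _ in range(2):
            w, sampler = _small_setup()
            scheme = fourd.calibrate_trigger_levels(w, 4)
            timeline, _ = fourd.simulate_triggered_acquisition(
                sampler, w, scheme, n_slices=4, tr_ms=2000.0)
            runs.append(timeline.events)
        pd.testing.assert_frame_equal(runs[0], runs[1])


class TestDutyCycle:
    def test_worked_example_220_over_440(self):
        # 110 windows of 2 s = 220 s nominal inside a 440 s scan
        ev = pd.DataFrame({"t_s": np.arange(110) * 4.0, "slice": 0,
                           "phase": 0, "window_s": 2.0})
        timeline = fourd.AcquisitionTimeline(ev, nominal_time_s=220.0,
                                             overall_time_s=440.0,
                                             calibration_time_s=6.0)
        assert fourd.duty_cycle(timeline) == pytest.approx(0.5)

    def test_back_to_back_unity(self):
        ev = pd.DataFrame({"t_s": np.arange(10) * 2.0, "slice": 0,
                           "phase": 0, "window_s": 2.0})
        timeline = fourd.AcquisitionTimeline(ev, 20.0, 20.0, 6.0)
        assert fourd.duty_cycle(timeline) == pytest.approx(1.0)

    def test_faster_breathing_higher_duty(self):
        duties = {}
        for period in (3.0, 5.0):
            w, sampler = _small_setup(period=period)
            scheme = fourd.calibrate_trigger_levels(w, 4)
            timeline, _ = fourd.simulate_triggered_acquisition(
                sampler, w, scheme, n_slices=4, tr_ms=2000.0)
            duties[period] = fourd.duty_cycle(timeline)
        assert duties[3.0] > duties[5.0]
        # cycle-limited triggering: duty ratio approaches T5/T3 = 5/3
        assert duties[3.0] / duties[5.0] == pytest.approx(5.0 / 3.0, rel=0.25)


class TestMip:
    def test_single_phase_identity(self):
        w, sampler = _small_setup()
        frame = sampler.frame(1.0)
        phases = fourd.PhaseSortedVolumes([frame], ["0%"])
        np.testing.assert_array_equal(fourd.compute_mip(phases).data,
                                      frame.data)

    def test_mip_dominates_subsets(self):
        w, sampler = _small_setup()
        frames = [sampler.frame(t) for t in (0.5, 1.0, 1.5, 2.0)]
        phases = fourd.PhaseSortedVolumes(frames, list("abcd"))
        full = fourd.compute_mip(phases).data
        sub = fourd.compute_mip(phases, subset=[0, 2]).data
        assert np.all(full >= sub - 1e-9)

    def test_geometry_mismatch_raises(self):
        a = ImageVolume.centered((4, 4, 4), (1, 1, 1))
        b = ImageVolume.centered((5, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            fourd.PhaseSortedVolumes([a, b], ["0%", "50%"])

    def test_empty_subset_raises(self):
        a = ImageVolume.centered((4, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            fourd.compute_mip(fourd.PhaseSortedVolumes([a], ["0%"]), subset=[])


class TestObjectExtent:
    def test_static_cube_extent(self):
        w, sampler = _small_setup()
        w.a[:] = 0.0
        frame = sampler.frame(0.0)
        extent = fourd.object_extent(frame, axis=2)
        assert extent == pytest.approx(40.0, abs=frame.spacing[2])

    def test_threshold_choice_irrelevant_for_binary_object(self):
        w, sampler = _small_setup()
        frame = sampler.frame(0.0)
        lo = fourd.object_extent(frame, axis=2, threshold=0.5)
        hi = fourd.object_extent(frame, axis=2, threshold=0.99)
        assert lo == pytest.approx(hi, abs=2 * frame.spacing[2])

    def test_empty_volume_raises(self):
        vol = ImageVolume.centered((4, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            fourd.object_extent(vol)


@pytest.fixture(scope="module")
def study():
    w, sampler = _small_setup(n_phases=6, n_slices=4,
                              duration=2 * 3.0 + (4 * 6 + 4) * 3.0)
    return fourd.phase_count_study(sampler, w, [2, 4, 6],
                                   n_slices=4, tr_ms=2000.0)


class TestPhaseCountStudy:

    def test_extent_nondecreasing_with_phase_count(self, study):
        assert np.all(np.diff(study.mip_extent_mm.values) >= 0)

    def test_captured_excursion_law(self, study):
        # MIP extent ~ object + excursion (N-1)/N, within one voxel (2 mm)
        for _, row in study.iterrows():
            law = 40.0 + 20.0 * (row.n_phases - 1) / row.n_phases
            assert row.mip_extent_mm == pytest.approx(law, abs=2.0)

    def test_overall_time_grows_with_phase_count(self, study):
        assert np.all(np.diff(study.overall_time_s.values) > 0)

    def test_unsorted_counts_rejected(self):
        w, sampler = _small_setup()
        with pytest.raises(ValueError):
            fourd.phase_count_study(sampler, w, [4, 2])
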