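import numpy as np
import pytest

from gaitclass.core import ImuRecording, SITES, TRIAL_TUG
from gaitclass.pipeline import cohort_to_samples
from gaitclass.segmentation import (
    IcParams,
    combined_acceleration,
    detect_initial_contacts,
    extract_gait_cycles,
    extract_walking_intervals,
    highpass_acceleration,
    read_cohort,
    segment_recording,
    segment_tug_phases,
)
from gaitclass.synthetic import CohortConfig, generate_cohort, generate_subject, write_cohort


def _recording(data_chest=None, n=600, fs=120.0, trial_type="10MWT"):
    data = {site: np.zeros((n, 6)) for site in SITES}
    if data_chest is not None:
        data["chest"] = data_chest
    return ImuRecording("S001", trial_type, 1, fs, data)


class TestHighpass:
    def test_constant_offset_removed(self):
        chest = np.zeros((600, 6))
        chest[:, 2] = 9.81
        out = highpass_acceleration(_recording(chest))
        assert abs(out.data["chest"][:, 2].mean()) < 1e-3 * 9.81

    def test_5hz_sine_amplitude_preserved(self):
        t = np.arange(1200) / 120.0
        chest = np.zeros((1200, 6))
        chest[:, 0] = np.sin(2 * np.pi * 5.0 * t)
        out = highpass_acceleration(_recording(chest, n=1200))
        mid = out.data["chest"][200:-200, 0]
        assert abs(np.abs(mid).max() - 1.0) < 0.05

    def test_gyro_bitwise_unchanged(self, wa_subject):
        recordings, _ = wa_subject
        rec = recordings[0]
        out = highpass_acceleration(rec)
        for site in SITES:
            assert np.array_equal(out.data[site][:, 3:], rec.data[site][:, 3:])

    def test_length_preserved(self, wa_subject):
        rec = wa_subject[0][0]
        assert highpass_acceleration(rec).n_samples == rec.n_samples

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_acceleration(_recording(), cutoff_hz=70.0)


class TestCombinedAcceleration:
    def test_pythagorean_triple(self):
        assert combined_acceleration(np.array([3.0]), np.array([4.0]),
                                     np.array([0.0]))[0] == pytest.approx(5.0)

    def test_zero(self):
        assert combined_acceleration(np.zeros(4), np.zeros(4), np.zeros(4)).max() == 0.0

    def test_unit_vector(self):
        out = combined_acceleration(np.ones(2), np.ones(2), np.ones(2))
        np.testing.assert_allclose(out, np.sqrt(3.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combined_acceleration(np.zeros(3), np.zeros(4), np.zeros(3))


class TestDetectInitialContacts:
    def test_recovers_ground_truth(self, wa_subject, default_config):
        recordings, truth = wa_subject
        fs = default_config.sample_rate_hz
        for rec in recordings:
            filtered = highpass_acceleration(rec)
            ics = detect_initial_contacts(filtered.data["left_ankle"], fs)
            true = truth.trials[rec.key()].ic_left
            assert len(ics) == len(true)
            assert np.abs(ics - true).max() / fs <= 0.025 + 1e-9

    def test_constant_signal_zero_ics(self):
        ankle = np.full((500, 6), 0.3)
        assert detect_initial_contacts(ankle, 120.0).size == 0

    def test_amplitude_invariance(self, wa_subject, default_config):
        rec = wa_subject[0][0]
        fs = default_config.sample_rate_hz
        filtered = highpass_acceleration(rec)
        ankle = filtered.data["left_ankle"]
        base = detect_initial_contacts(ankle, fs)
        doubled = detect_initial_contacts(ankle * 2.0, fs)
        assert np.array_equal(base, doubled)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            detect_initial_contacts(np.zeros((2, 6)), 120.0)


@pytest.fixture(scope="module")
def tug_case(wa_subject, default_config):
    recordings, truth = wa_subject
    rec = next(r for r in recordings if r.trial_type == TRIAL_TUG)
    filtered = highpass_acceleration(rec)
    phases = segment_tug_phases(filtered.data["lower_back"],
                                default_config.sample_rate_hz)
    return filtered, phases, truth.trials[rec.key()].tug_phases


class TestSegmentTugPhases:
    def test_boundaries_within_100ms(self, tug_case, default_config):
        _, detected, true = tug_case
        fs = default_config.sample_rate_hz
        for got, want in zip(detected.ordered(), true.ordered()):
            assert abs(got[0] - want[0]) / fs <= 0.1
            assert abs(got[1] - want[1]) / fs <= 0.1

    def test_phases_ordered_and_non_overlapping(self, tug_case):
        _, detected, _ = tug_case
        detected.validate()

    def test_turn_contains_yaw_abs_maximum(self, tug_case):
        filtered, detected, _ = tug_case
        yaw = np.abs(filtered.data["lower_back"][:, 5])
        anchor = int(np.argmax(yaw))
        turns = [detected.turn1, detected.turn2]
        assert any(s <= anchor < e for (s, e) in turns)

    def test_single_burst_rejected(self):
        lumbar = np.zeros((1200, 6))
        t = np.arange(1200) / 120.0
        lumbar[:, 4] = np.exp(-((t - 2.0) ** 2) / 0.1) - np.exp(-((t - 8.0) ** 2) / 0.1)
        lumbar[:, 5] = np.exp(-((t - 5.0) ** 2) / 0.1)  # only one yaw burst
        lumbar += np.random.default_rng(0).normal(0, 1e-4, lumbar.shape)
        with pytest.raises(ValueError, match="yaw"):
            segment_tug_phases(lumbar, 120.0)


class TestWalkingIntervals:
    def test_tug_yields_two_intervals(self, wa_subject, default_config):
        recordings, truth = wa_subject
        rec = next(r for r in recordings if r.trial_type == TRIAL_TUG)
        phases = truth.trials[rec.key()].tug_phases
        intervals = extract_walking_intervals(rec, tug_phases=phases)
        assert intervals == [phases.walk1, phases.walk2]
        # walking intervals never overlap the turns
        for (lo, hi) in intervals:
            for (ts, te) in (phases.turn1, phases.turn2):
                assert hi <= ts or lo >= te

    def test_mwt_first_and_last_cycle_dropped(self):
        rec = _recording()
        ics = np.arange(11) * 50  # 10 detected cycles
        intervals = extract_walking_intervals(rec, ic_left=ics)
        assert intervals == [(50, 450)]  # cycles 2..9 retained

    def test_mwt_too_few_cycles(self):
        with pytest.raises(ValueError, match="3"):
            extract_walking_intervals(_recording(), ic_left=np.array([0, 50, 100]))


class TestExtractGaitCycles:
    def test_five_ics_give_four_windows(self, wa_subject):
        rec = wa_subject[0][0]
        ics = np.array([100, 230, 360, 490, 620])
        windows = extract_gait_cycles(rec, [(0, 1000)], ics, label="WA")
        assert len(windows) == 4
        assert all(w.data.shape[1] == 48 for w in windows)

    def test_tug_step_arithmetic(self, default_config):
        # 4 cycles in walk1 and 3 in walk2 -> 5 + 4 ICs -> 7 windows
        config = CohortConfig(missing_tug_fraction=0.0, tug_walk_cycles=(4, 3))
        recordings, truth = generate_subject("WA", config, seed=2)
        rec = next(r for r in recordings if r.trial_type == TRIAL_TUG)
        tt = truth.trials[rec.key()]
        intervals = extract_walking_intervals(rec, tug_phases=tt.tug_phases)
        windows = extract_gait_cycles(rec, intervals, tt.ic_left, label="WA")
        assert len(windows) == 7

    def test_windows_inside_intervals(self, wa_subject, default_config):
        recordings, _ = wa_subject
        windows = segment_recording(recordings[0], "WA")
        max_len = max(w.length for w in windows)
        assert all(2 <= w.length <= max_len for w in windows)

    def test_deterministic(self, wa_subject):
        rec = wa_subject[0][0]
        a = segment_recording(rec, "WA")
        b = segment_recording(rec, "WA")
        assert len(a) == len(b)
        for wa, wb in zip(a, b):
            assert (wa.start, wa.end) == (wb.start, wb.end)
            assert np.array_equal(wa.data, wb.data)


class TestReadCohort:
    def test_missing_site_file_named_in_error(self, tmp_path):
        cohort = generate_cohort(CohortConfig.desk_scale(1, 1, seed=0))
        manifest = write_cohort(cohort, tmp_path)
        victim = next(tmp_path.rglob("left_ankle.csv"))
        victim.unlink()
        with pytest.raises(FileNotFoundError, match="left_ankle"):
            read_cohort(manifest)

    def test_missing_tug_subject_loaded_with_mwt_only(self, tmp_path):
        config = CohortConfig.desk_scale(1, 1, seed=0)
        config.missing_tug_fraction = 1.0
        manifest = write_cohort(generate_cohort(config), tmp_path)
        cohort = read_cohort(manifest)
        for subject in cohort:
            assert {r.trial_type for r in subject.recordings} == {"10MWT"}

    def test_missing_tug_subject_not_dropped_from_pipeline(self, tmp_path):
        config = CohortConfig.desk_scale(2, 2, seed=0)
        config.missing_tug_fraction = 1.0
        manifest = write_cohort(generate_cohort(config), tmp_path)
        cohort = read_cohort(manifest)
        samples = cohort_to_samples(cohort)
        assert len(samples) == 4  # everyone contributes 10MWT windows
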