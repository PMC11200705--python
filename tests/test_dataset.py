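import numpy as np
import pytest

from gaitclass.core import N_CHANNELS, NormalizedSample, SITES, site_channel_slice
from gaitclass.dataset import (
    assemble_fold,
    augment,
    load_samples,
    mask_sensors,
    normalize_windows,
    pad_window,
    save_samples,
)
from tests.conftest import make_window


def _window_with_group_values(values, axis=0, n=4):
    """Window whose acc-axis ``axis`` group holds ``values``; other groups
    are filled with ones so no denominator is zero."""
    data = np.zeros((n, N_CHANNELS))
    for other in range(6):
        if other != axis:
            data[:, other] = 1.0  # chest channel of each remaining group
    for i, v in enumerate(values):
        data[i, axis + 6 * (i % 8)] = v
    return make_window(data)


class TestNormalizeWindows:
    def test_negative_extremum_gives_min_zero(self):
        w = _window_with_group_values([-2.0, 1.0])
        (out,) = normalize_windows([w])
        group = out.data[:, np.arange(0, N_CHANNELS, 6)]
        assert group.min() == pytest.approx(0.0)       # -2/2/2 + 0.5
        assert np.isclose(group, 0.75).any()           # 1/2/2 + 0.5

    def test_positive_extremum_gives_max_one(self):
        w = _window_with_group_values([1.0, 2.0])
        (out,) = normalize_windows([w])
        group = out.data[:, np.arange(0, N_CHANNELS, 6)]
        assert group.max() == pytest.approx(1.0)
        assert np.isclose(group, 0.75).any()

    def test_outputs_in_unit_interval(self, rng):
        windows = [make_window(rng.normal(0, 5, (30, N_CHANNELS))) for _ in range(4)]
        for out in normalize_windows(windows):
            assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_extremum_attained_per_group(self, rng):
        windows = [make_window(rng.normal(0, 5, (30, N_CHANNELS))) for _ in range(4)]
        outs = normalize_windows(windows)
        stacked = np.vstack([o.data for o in outs])
        for axis in range(6):
            group = stacked[:, np.arange(axis, N_CHANNELS, 6)]
            assert np.isclose(group.min(), 0.0) or np.isclose(group.max(), 1.0)

    def test_sign_structure_preserved(self, rng):
        data = rng.normal(0, 2, (20, N_CHANNELS))
        (out,) = normalize_windows([make_window(data)])
        assert np.all((data > 0) == (out.data > 0.5))
        assert np.all(out.data[data == 0.0] == 0.5)

    def test_all_zero_group_rejected(self):
        data = np.ones((5, N_CHANNELS))
        data[:, np.arange(3, N_CHANNELS, 6)] = 0.0  # zero out gyr_roll group
        with pytest.raises(ValueError, match="zero"):
            normalize_windows([make_window(data)])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_windows([])


class TestPadWindow:
    def _normalized(self, n):
        return make_window(np.full((n, N_CHANNELS), 0.6))

    def test_pad_to_276(self):
        sample = pad_window(self._normalized(100), length_max=276)
        assert sample.matrix.shape == (276, N_CHANNELS)
        assert np.all(sample.matrix[100:] == 0.5)
        assert np.all(sample.matrix[:100] == 0.6)
        assert sample.valid_length == 100

    def test_exact_length_identity(self):
        sample = pad_window(self._normalized(276), length_max=276)
        assert np.all(sample.matrix == 0.6)

    def test_longer_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pad_window(self._normalized(277), length_max=276)

    def test_pad_then_crop_recovers_window(self, rng):
        data = rng.random((60, N_CHANNELS))
        sample = pad_window(make_window(data), length_max=120)
        np.testing.assert_array_equal(sample.matrix[:60], data)


def _samples(n=5, length=20, rng=None, label="WA", subject="S001"):
    rng = rng or np.random.default_rng(0)
    out = []
    for _ in range(n):
        m = rng.random((length, N_CHANNELS)) * 0.5 + 0.25
        out.append(NormalizedSample(m, subject, label, valid_length=length).validate())
    return out


class TestAugment:
    def test_five_fold_increase(self):
        assert len(augment(_samples(200 // 10) * 10, n_copies=4)) == 1000

    def test_zero_copies_identity(self):
        samples = _samples(3)
        assert augment(samples, n_copies=0) == samples

    def test_noise_bound(self):
        samples = _samples(4)
        out = augment(samples, n_copies=2, seed=1, clip=False)
        for orig, noisy in zip(samples * 2, out[4:]):
            assert np.abs(noisy.matrix - orig.matrix).max() <= 0.1

    def test_clipped_to_unit_interval(self):
        samples = _samples(4)
        out = augment(samples, n_copies=3, seed=1)
        for s in out:
            assert s.matrix.min() >= 0.0 and s.matrix.max() <= 1.0

    def test_reproducible(self):
        samples = _samples(2)
        a = augment(samples, seed=7)
        b = augment(samples, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.matrix, y.matrix)

    def test_copies_keep_label_and_subject(self):
        samples = _samples(2, label="NA", subject="S009")
        for s in augment(samples, n_copies=2, seed=0):
            assert s.label == "NA" and s.subject_id == "S009"

    def test_originals_untouched(self):
        samples = _samples(2)
        before = [s.matrix.copy() for s in samples]
        augment(samples, n_copies=3, seed=0)
        for s, m in zip(samples, before):
            assert np.array_equal(s.matrix, m)

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            augment(_samples(1), n_copies=-1)


class TestMaskSensors:
    def test_exclude_right_ankle(self):
        (s,) = _samples(1)
        out = mask_sensors(s, ["right_ankle"])
        assert np.all(out.matrix[:, site_channel_slice("right_ankle")] == 0.5)
        kept = [i for i in range(N_CHANNELS)
                if i not in range(*site_channel_slice("right_ankle").indices(N_CHANNELS))]
        assert np.array_equal(out.matrix[:, kept], s.matrix[:, kept])

    def test_empty_exclusion_identity(self):
        (s,) = _samples(1)
        out = mask_sensors(s, [])
        assert np.array_equal(out.matrix, s.matrix)

    def test_exclude_all_but_two(self):
        (s,) = _samples(1)
        excluded = [site for site in SITES if site not in ("right_ankle", "right_wrist")]
        out = mask_sensors(s, excluded)
        assert int((out.matrix == 0.5).all(axis=0).sum()) >= 36

    def test_unknown_site(self):
        with pytest.raises(ValueError, match="unknown"):
            mask_sensors(_samples(1)[0], ["head"])

    def test_mask_commutes_with_padding(self, rng):
        data = rng.random((30, N_CHANNELS)) * 0.5 + 0.25
        w = make_window(data)
        a = mask_sensors(pad_window(w, 50), ["chest"])
        masked_window = make_window(data.copy())
        masked_window.data[:, site_channel_slice("chest")] = 0.5
        b = pad_window(masked_window, 50)
        assert np.array_equal(a.matrix, b.matrix)


class TestAssembleFold:
    @pytest.fixture
    def cohort_samples(self):
        samples = []
        rng = np.random.default_rng(3)
        for i, label in enumerate(["WA"] * 4 + ["NA"] * 3):
            samples += _samples(6, rng=rng, label=label, subject=f"S{i:02d}")
        return samples

    def test_balanced_train_labels(self, cohort_samples):
        train, val, _ = assemble_fold(cohort_samples, "S00", seed=0, n_copies=0)
        pool = train + val
        counts = {lab: sum(s.label == lab for s in pool) for lab in ("WA", "NA")}
        assert counts["WA"] == counts["NA"]

    def test_no_leakage(self, cohort_samples):
        train, val, test = assemble_fold(cohort_samples, "S02", seed=0)
        assert all(s.subject_id == "S02" for s in test)
        assert all(s.subject_id != "S02" for s in train + val)

    def test_test_set_never_augmented(self, cohort_samples):
        _, _, test = assemble_fold(cohort_samples, "S02", seed=0, n_copies=4)
        assert len(test) == 6

    def test_train_augmented_five_fold(self, cohort_samples):
        train0, val0, _ = assemble_fold(cohort_samples, "S00", seed=5, n_copies=0)
        train4, val4, _ = assemble_fold(cohort_samples, "S00", seed=5, n_copies=4)
        assert len(val4) == len(val0)
        assert len(train4) == 5 * len(train0)

    def test_absent_subject_rejected(self, cohort_samples):
        with pytest.raises(ValueError, match="held-out"):
            assemble_fold(cohort_samples, "S99")

    def test_single_class_remainder_rejected(self):
        samples = _samples(4, label="WA", subject="S01") + _samples(4, label="NA", subject="S02")
        with pytest.raises(ValueError, match="both labels"):
            assemble_fold(samples, "S02")


class TestHdf5RoundTrip:
    def test_save_load(self, tmp_path):
        samples = _samples(5, label="NA")
        path = tmp_path / "windows.h5"
        save_samples(samples, path)
        loaded = load_samples(path)
        assert len(loaded) == 5
        for a, b in zip(samples, loaded):
            assert np.array_equal(a.matrix, b.matrix)
            assert (a.subject_id, a.label, a.valid_length) == (
                b.subject_id, b.label, b.valid_length)
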