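import numpy as np
import pytest

from backaverage import (
    ChannelPair,
    MarkerSet,
    SegmentSpec,
    average,
    baseline_correct,
    segment,
    split_half,
)
from backaverage.epoch import SegmentSet, measure_trough, split_half_similarities

FS = 1000.0
SPEC = SegmentSpec(window_s=3.0, onset_s=2.0, baseline_s=0.5)


def _pair(n=10000, rng=None):
    rng = rng or np.random.default_rng(0)
    return ChannelPair(emg=rng.standard_normal(n), eeg=rng.standard_normal(n), fs=FS)


def _segset(eeg, fs=FS, spec=SPEC):
    """SegmentSet built directly from an epoch stack (EMG mirrors EEG)."""
    n = eeg.shape[0]
    on = spec.onset_sample(fs)
    markers = MarkerSet(indices=np.arange(n) * eeg.shape[1] + on, fs=fs,
                        provenance="ground_truth")
    return SegmentSet(eeg=eeg, emg=eeg.copy(), kept_markers=markers, dropped=0,
                      fs=fs, spec=spec)


class TestSegment:
    def test_index_arithmetic(self):
        pair = _pair(10000)
        markers = MarkerSet(indices=[2500, 6000], fs=FS)
        segs = segment(pair, markers, SPEC)
        assert segs.eeg.shape == (2, 3000)
        np.testing.assert_array_equal(segs.eeg[0], pair.eeg[500:3500])
        np.testing.assert_array_equal(segs.eeg[1], pair.eeg[4000:7000])
        np.testing.assert_array_equal(segs.emg[0], pair.emg[500:3500])
        assert segs.dropped == 0

    def test_edge_markers_dropped_and_counted(self):
        pair = _pair(10000)
        markers = MarkerSet(indices=[1000, 5000, 9500], fs=FS)
        segs = segment(pair, markers, SPEC)  # first starts at -1000, last overruns
        assert segs.n_kept == 1
        assert segs.dropped == 2
        np.testing.assert_array_equal(segs.kept_markers.indices, [5000])

    def test_all_dropped_is_error(self):
        pair = _pair(4000)
        with pytest.raises(ValueError, match="no complete segments"):
            segment(pair, MarkerSet(indices=[100], fs=FS), SPEC)

    def test_window_longer_than_record_error(self):
        pair = _pair(2000)
        with pytest.raises(ValueError, match="exceeds the record"):
            segment(pair, MarkerSet(indices=[1000], fs=FS), SPEC)

    def test_shift_equivariance(self, rng):
        """Shifting every marker by k samples shifts the average by k."""
        pair = _pair(20000, rng)
        k = 17
        m1 = MarkerSet(indices=[3000, 9000, 15000], fs=FS)
        m2 = MarkerSet(indices=m1.indices + k, fs=FS)
        a1 = average(segment(pair, m1, SPEC))
        a2 = average(segment(pair, m2, SPEC))
        np.testing.assert_allclose(a1.eeg_mean[k:], a2.eeg_mean[:-k], rtol=1e-12)


class TestBaselineCorrect:
    def test_subtracts_early_mean(self):
        spec = SegmentSpec(window_s=0.004, onset_s=0.003, baseline_s=0.002)
        segs = _segset(np.array([[5.0, 5.0, 5.0, 9.0]]), spec=spec)
        out = baseline_correct(segs)
        np.testing.assert_allclose(out.eeg[0], [0.0, 0.0, 0.0, 4.0])
        # EMG untouched
        np.testing.assert_allclose(out.emg[0], [5.0, 5.0, 5.0, 9.0])

    def test_zero_segment_unchanged(self):
        segs = _segset(np.zeros((3, 3000)))
        np.testing.assert_array_equal(baseline_correct(segs).eeg, 0.0)

    def test_baseline_window_mean_is_zero(self, rng):
        segs = _segset(rng.standard_normal((7, 3000)))
        out = baseline_correct(segs)
        nb = int(round(SPEC.baseline_s * FS))
        np.testing.assert_allclose(out.eeg[:, :nb].mean(axis=1), 0.0, atol=1e-9)
        assert out.baseline_applied

    def test_double_application_rejected(self, rng):
        segs = baseline_correct(_segset(rng.standard_normal((3, 3000))))
        with pytest.raises(ValueError, match="already applied"):
            baseline_correct(segs)

    def test_baseline_past_onset_rejected(self, rng):
        segs = _segset(rng.standard_normal((3, 3000)))
        with pytest.raises(ValueError, match="past the onset"):
            baseline_correct(segs, baseline_s=2.5)


class TestAverage:
    def test_identical_segments_average_to_segment(self, rng):
        seg = rng.standard_normal(3000)
        avg = average(_segset(np.tile(seg, (5, 1))))
        np.testing.assert_allclose(avg.eeg_mean, seg, rtol=1e-12)
        assert avg.n == 5

    def test_two_segment_mean(self):
        spec = SegmentSpec(window_s=0.002, onset_s=0.001, baseline_s=0.001)
        avg = average(_segset(np.array([[0.0, 2.0], [2.0, 0.0]]), spec=spec))
        np.testing.assert_allclose(avg.eeg_mean, [1.0, 1.0])

    def test_matches_naive_two_loop_mean(self, rng):
        """Independent oracle: explicit per-sample accumulation."""
        stack = rng.standard_normal((13, 300))
        spec = SegmentSpec(window_s=0.3, onset_s=0.2, baseline_s=0.1)
        avg = average(_segset(stack, spec=spec))
        naive = np.empty(300)
        for j in range(300):
            acc = 0.0
            for i in range(13):
                acc += stack[i, j]
            naive[j] = acc / 13
        np.testing.assert_allclose(avg.eeg_mean, naive, atol=1e-12)

    def test_time_axis_zero_at_onset(self, rng):
        avg = average(_segset(rng.standard_normal((2, 3000))))
        on = SPEC.onset_sample(FS)
        assert abs(avg.time_s[on]) < 1 / (2 * FS)
        assert avg.time_s[0] == pytest.approx(-2.0)

    def test_white_noise_suppression(self, rng):
        """Averaging 100 unit-variance noise epochs leaves ~1/sqrt(100) noise."""
        avg = average(_segset(rng.standard_normal((100, 3000))))
        assert avg.eeg_mean.std() <= 0.15

    @pytest.mark.parametrize("n", [10, 40, 100])
    def test_sqrt_n_rms_scaling(self, n):
        rng = np.random.default_rng(n)
        stack = rng.standard_normal((n, 3000))
        avg = average(_segset(stack))
        rms_avg = np.sqrt(np.mean(avg.eeg_mean**2))
        rms_single = np.sqrt(np.mean(stack**2))
        assert 0.5 / np.sqrt(n) <= rms_avg / rms_single <= 2.0 / np.sqrt(n)


class TestSplitHalf:
    def test_identical_segments_fully_consistent(self, rng):
        seg = rng.standard_normal(3000)
        sh = split_half(_segset(np.tile(seg, (6, 1))), seed=1)
        np.testing.assert_allclose(sh.avg_a.eeg_mean, sh.avg_b.eeg_mean)
        assert sh.similarity == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        segs = _segset(rng.standard_normal((9, 3000)))
        sh1 = split_half(segs, seed=42)
        sh2 = split_half(segs, seed=42)
        np.testing.assert_array_equal(sh1.assignment, sh2.assignment)
        assert sh1.similarity == sh2.similarity
        np.testing.assert_array_equal(sh1.avg_a.eeg_mean, sh2.avg_a.eeg_mean)

    def test_groups_partition_segments(self, rng):
        segs = _segset(rng.standard_normal((9, 3000)))
        sh = split_half(segs, seed=3)
        assert sorted(sh.assignment) == list(range(9))
        assert sh.avg_a.n == 5  # odd n: group A gets the extra epoch
        assert sh.avg_b.n == 4

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            split_half(_segset(rng.standard_normal((1, 3000))), seed=0)

    def test_similarity_family_reproducible(self, rng):
        segs = _segset(rng.standard_normal((8, 3000)))
        a = split_half_similarities(segs, n_splits=5, seed=10)
        b = split_half_similarities(segs, n_splits=5, seed=10)
        np.testing.assert_array_equal(a, b)
        assert np.all((a >= -1) & (a <= 1))


class TestMeasureTrough:
    def test_finds_planted_trough(self):
        fs = 1000.0
        spec = SegmentSpec(window_s=3.0, onset_s=2.0, baseline_s=0.5)
        t = (np.arange(3000) - 2000) / fs
        # descend to -8 at onset, recover to 0 over the next 0.5 s
        y = np.where(t < 0, -4.0 * (t + 2), np.minimum(-8.0 + 16.0 * t, 0.0))
        stack = np.tile(y, (4, 1))
        amp, lat = measure_trough(average(_segset(stack, fs=fs, spec=spec)))
        assert amp == pytest.approx(-8.0, rel=0.05)
        assert -0.05 <= lat <= 0.05
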