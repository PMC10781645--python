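import numpy as np
import pytest

from ultraseq.preprocess import (ShuffleSpec, binarize_activity,
                                 binarize_spike_trains, compute_snr,
                                 gaussian_kernel, gaussian_smooth,
                                 make_shuffle)
from ultraseq.session import EventMatrix


class TestBinarize:
    def test_constant_trace_yields_zeros(self):
        out = binarize_activity(np.full((1, 40), 3.0), 0.129)
        assert out.values.sum() == 0

    def test_hand_example_pins_population_sd(self):
        # downsampled trace [0, 0, 8]: mean 2.667, population SD 3.771,
        # threshold 8.32 -> nothing strictly above
        trace = np.array([[0, 0, 0, 0, 0, 0, 0, 0, 8, 8, 8, 8]], dtype=float)
        out = binarize_activity(trace, 0.129, downsample_factor=4)
        np.testing.assert_array_equal(out.values, [[0, 0, 0]])
        assert out.bin_size == pytest.approx(0.516)

    def test_event_fraction_non_increasing_in_threshold(self, rng):
        trace = rng.gamma(1.0, 1.0, size=(1, 4000))
        fractions = [binarize_activity(trace, 0.129, k_sd=k).values.mean()
                     for k in (0.5, 1.0, 1.5, 2.0)]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestSnr:
    def test_no_activity_gives_zero(self):
        flat = np.zeros(200)
        assert compute_snr(flat, flat, bin_size=0.129) == 0.0

    def test_constructed_trace_gives_five(self):
        # one activity burst of mean 10; noise of SD 2 far from the burst
        bin_size = 0.5
        n = 200
        deconv = np.zeros(n)
        deconv[100:104] = 5.0
        # +-2 alternation has SD exactly 2 over the (balanced) noise bins
        f_corr = np.tile([2.0, -2.0], n // 2)
        f_corr[100:104] = 10.0
        snr = compute_snr(f_corr, deconv, bin_size=bin_size)
        assert snr == pytest.approx(5.0, rel=1e-6)

    def test_scale_invariance(self, rng):
        deconv = rng.random(500)
        deconv[200:205] += 30
        f_corr = rng.normal(0, 1, 500) + deconv
        a = compute_snr(f_corr, deconv, 0.129)
        b = compute_snr(3.7 * f_corr, deconv, 0.129)
        assert a == pytest.approx(b, rel=1e-9)


class TestSmoothing:
    def test_impulse_gives_unit_mass_gaussian(self):
        row = np.zeros((1, 201))
        row[0, 100] = 1.0
        sm = gaussian_smooth(row, width_s=2.0, bin_size=0.129)
        assert sm.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(sm[0]) == 100

    def test_interior_mass_preserved(self, rng):
        row = np.zeros((1, 500))
        row[0, 200:300] = rng.random(100)
        sm = gaussian_smooth(row, width_s=1.0, bin_size=0.129)
        assert sm.sum() == pytest.approx(row.sum(), abs=1e-9)

    def test_two_impulses_resolved(self):
        width = 2.0
        bin_size = 0.129
        row = np.zeros((1, 400))
        sep = int(round(2 * width / bin_size))
        row[0, 100] = row[0, 100 + sep] = 1.0
        sm = gaussian_smooth(row, width, bin_size)[0]
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(sm)
        assert len(peaks) == 2

    def test_kernel_is_matlab_window_convention(self):
        k = gaussian_kernel(5.0, 0.129)
        sd_bins = 5.0 / 0.129 / 5.0
        assert k.size == 2 * int(np.ceil(2.5 * sd_bins)) + 1
        assert k.sum() == pytest.approx(1.0)


class TestShuffles:
    @pytest.fixture()
    def events(self, rng):
        return EventMatrix((rng.random((8, 400)) < 0.1).astype(int), 0.129)

    @pytest.mark.parametrize("spec", [
        ShuffleSpec(kind="temporal"),
        ShuffleSpec(kind="circular"),
        ShuffleSpec(kind="epoch", epoch_length=5.0),
    ], ids=["temporal", "circular", "epoch"])
    def test_per_cell_event_counts_preserved(self, events, spec, rng):
        out = make_shuffle(events, spec, rng)
        np.testing.assert_array_equal(out.values.sum(axis=1),
                                      events.values.sum(axis=1))

    def test_single_epoch_shuffle_is_identity(self, events, rng):
        spec = ShuffleSpec(kind="epoch", epoch_length=events.duration)
        out = make_shuffle(events, spec, rng)
        np.testing.assert_array_equal(out.values, events.values)

    def test_epoch_longer_than_session_rejected(self, events, rng):
        spec = ShuffleSpec(kind="epoch", epoch_length=events.duration * 2)
        with pytest.raises(ValueError):
            make_shuffle(events, spec, rng)

    def test_one_bin_epochs_match_temporal_shuffle_in_distribution(self, rng):
        # epoch shuffling with single-bin epochs is a full permutation;
        # the spectral flatness of the two nulls must be indistinguishable
        from scipy.stats import ks_2samp
        from ultraseq.spectral import welch_psd
        row = (rng.random(256) < 0.2).astype(int)
        events = EventMatrix(row[None, :], 0.129)

        def flatness(spec):
            stats = []
            for _ in range(100):
                out = make_shuffle(events, spec, rng).values[0].astype(float)
                _, psd = welch_psd(out - out.mean(), fs=1 / 0.129,
                                   window_bins=128)
                stats.append(psd.max() / psd.mean())
            return np.array(stats)

        a = flatness(ShuffleSpec(kind="temporal"))
        b = flatness(ShuffleSpec(kind="epoch", epoch_length=0.129))
        assert ks_2samp(a, b).pvalue > 0.01

    def test_circular_shuffle_preserves_autocorrelation(self, rng):
        row = (rng.random(200) < 0.15).astype(int)
        events = EventMatrix(row[None, :], 0.129)
        out = make_shuffle(events, ShuffleSpec(kind="circular"), rng)

        def circular_autocorr(x):
            x = x - x.mean()
            return np.array([np.dot(x, np.roll(x, lag)) for lag in range(x.size)])

        np.testing.assert_allclose(circular_autocorr(out.values[0].astype(float)),
                                   circular_autocorr(row.astype(float)),
                                   atol=1e-9)


class TestSpikeBinarization:
    def test_all_zero_counts_stay_zero(self):
        counts = np.zeros((3, 20000), dtype=int)
        out = binarize_spike_trains(counts)
        assert out.values.sum() == 0

    def test_initial_segment_dropped(self):
        n = int(40 * 60 / 0.120)          # 40 minutes
        counts = np.zeros((2, n), dtype=int)
        out = binarize_spike_trains(counts)
        assert out.n_bins == n - int(300 / 0.120)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError):
            binarize_spike_trains(np.zeros((2, 100), dtype=int))

    def test_smoothing_extends_event_runs(self, rng):
        n = int(40 * 60 / 0.120)
        t = np.arange(n) * 0.120
        rate = 2.0 * (1 + np.sin(2 * np.pi * t / 120.0))
        counts = rng.poisson(rate)[None, :]
        smoothed = binarize_spike_trains(counts, smooth_width=5.0)
        raw = binarize_spike_trains(counts, smooth_width=None)

        def max_run(x):
            best = run = 0
            for v in x:
                run = run + 1 if v else 0
                best = max(best, run)
            return best

        assert max_run(smoothed.values[0]) >= max_run(raw.values[0])
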