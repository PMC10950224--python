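"""Signal-conditioning contracts: closed forms and brute-force oracles."""

import numpy as np
import pytest

from heartmil import preprocess as pp
from heartmil.segmentation import Interval, PhaseSegmentation

RATE = 2000.0


def tone(freq, dur=2.0, amp=1.0, rate=RATE):
    return amp * np.sin(2 * np.pi * freq * np.arange(int(dur * rate)) / rate)


class TestResample:
    def test_identity_and_constant(self):
        x = np.linspace(-1, 1, 100)
        assert np.array_equal(pp.resample(x, 500, 500), x)
        c = pp.resample(np.full(200, 0.7), 1000, 400)
        assert c.shape == (80,)
        assert np.allclose(c, 0.7)

    def test_ramp_matches_analytic_line(self):
        """Downsampling a ramp must evaluate the underlying line pointwise."""
        n_in = 4000
        x = np.arange(n_in) / (n_in - 1)  # line v(t) = t * 4000/3999 over 1 s
        out = pp.resample(x, 4000, 2000)
        assert out.shape == (2000,)
        t_out = np.arange(2000) / 2000.0
        assert np.allclose(out, t_out * 4000 / 3999, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pp.resample(np.array([]), 100, 50)


class TestQuality:
    def test_low_frequency_tone_not_noisy(self):
        report = pp.assess_quality(tone(50, amp=0.5), RATE)
        assert not report.noise_flags.any()
        assert not report.saturation_flags.any()
        assert report.usable_mask.all()

    def test_clipped_square_wave_saturated(self):
        x = np.clip(3 * tone(5), -1, 1)
        report = pp.assess_quality(x, RATE)
        assert report.saturation_flags.all()

    def test_high_band_noise_flagged(self, rng):
        x = pp.bandpass(rng.standard_normal(int(2 * RATE)), RATE,
                        pp.PreprocessConfig(band=(150.0, 240.0)))
        report = pp.assess_quality(x, RATE)
        assert report.noise_flags.all()

    def test_all_zero_signal_is_clean_by_convention(self):
        report = pp.assess_quality(np.zeros(int(2 * RATE)), RATE)
        assert not report.saturation_flags.any()
        assert not report.noise_flags.any()


class TestBandpass:
    def test_dc_rejected(self):
        out = pp.bandpass(np.full(4000, 0.8), RATE)
        assert np.max(np.abs(out)) < 1e-6 * 0.8

    def test_passband_tone_preserved_stopband_attenuated(self):
        """Output/input RMS measured directly as the oracle."""
        inside = pp.bandpass(tone(100), RATE)
        ratio_in = np.std(inside[1000:-1000]) / np.std(tone(100)[1000:-1000])
        assert abs(ratio_in - 1.0) < 0.05
        low_tone = tone(5, dur=4.0)
        outside = pp.bandpass(low_tone, RATE)
        ratio_out = np.std(outside[2000:-2000]) / np.std(low_tone[2000:-2000])
        assert ratio_out < 10 ** (-20 / 20)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(tone(100), 1200, pp.PreprocessConfig(band=(10, 800),
                                                             target_rate=1200))


class TestBestSegment:
    def _report(self, mask):
        return pp.QualityReport(np.zeros(1, bool), np.zeros(1, bool),
                                np.asarray(mask, bool), len(mask))

    def test_fully_usable_leftmost(self):
        q = self._report(np.ones(1000))
        assert pp.best_segment(np.zeros(1000), q, 300) == (0, 300)

    def test_matches_exhaustive_scan(self, rng):
        """Exhaustive window scan as the oracle on random masks."""
        for _ in range(20):
            mask = rng.random(400) < 0.5
            q = self._report(mask)
            L = 64
            start, end = pp.best_segment(np.zeros(400), q, L)
            counts = [mask[s:s + L].sum() for s in range(400 - L + 1)]
            assert mask[start:end].sum() == max(counts)
            assert start == int(np.argmax(counts))  # leftmost tie

    def test_unusable_falls_back_to_prefix(self):
        q = self._report(np.zeros(500))
        with pytest.warns(UserWarning):
            assert pp.best_segment(np.zeros(500), q, 100) == (0, 100)


def _segmentation_of_cycles(n_cycles, cycle=400):
    ivs = []
    t = 0
    for _ in range(n_cycles):
        for lab, ln in (("S1", 80), ("systole", 100), ("S2", 60), ("diastole", 160)):
            ivs.append(Interval(t, t + ln, lab))
            t += ln
    return PhaseSegmentation(ivs), t


class TestUsableCycles:
    def test_clean_cycles_all_counted(self):
        seg, n = _segmentation_of_cycles(10)
        q = pp.QualityReport(np.zeros(1, bool), np.zeros(1, bool),
                             np.ones(n, bool), n)
        assert pp.count_usable_cycles(seg, q) == 10
        assert pp.require_min_cycles(seg, q) == 10

    def test_two_cycles_rejected(self):
        seg, n = _segmentation_of_cycles(2)
        q = pp.QualityReport(np.zeros(1, bool), np.zeros(1, bool),
                             np.ones(n, bool), n)
        with pytest.raises(pp.RecordingRejected):
            pp.require_min_cycles(seg, q)

    def test_masked_middle_cycles_not_counted(self):
        """5 cycles with the middle 3 masked out leaves 2 -> rejected."""
        seg, n = _segmentation_of_cycles(5)
        mask = np.ones(n, bool)
        mask[400:1600] = False  # cycles 2-4 (cycle length 400)
        q = pp.QualityReport(np.zeros(1, bool), np.zeros(1, bool), mask, n)
        assert pp.count_usable_cycles(seg, q) == 2
        with pytest.raises(pp.RecordingRejected):
            pp.require_min_cycles(seg, q)


class TestDespike:
    def test_spike_free_signal_unchanged(self):
        x = tone(40, dur=3.0)
        assert np.max(np.abs(pp.despike(x, RATE) - x)) < 1e-9

    def test_spike_removed(self):
        x = tone(40, dur=3.0, amp=0.5)
        pre_max = np.max(np.abs(x))
        x_spiked = x.copy()
        x_spiked[3000:3003] += 10.0
        out = pp.despike(x_spiked, RATE)
        assert np.max(np.abs(out)) < 2 * pre_max

    def test_zeros_unchanged(self):
        assert np.array_equal(pp.despike(np.zeros(2000), RATE), np.zeros(2000))


class TestClipEdges:
    @pytest.mark.parametrize("dur,expected_cut", [(5.0, 0.0), (30.0, 3.0),
                                                  (17.5, 1.5)])
    def test_linear_rule_closed_form(self, dur, expected_cut):
        n = int(dur * RATE)
        out = pp.clip_edges(np.arange(n, dtype=float), RATE)
        cut = int(round(expected_cut * RATE))
        assert len(out) == n - 2 * cut
        assert out[0] == cut  # contiguous sub-interval, values unmodified

    def test_too_short_returns_uncut_with_warning(self):
        x = np.ones(int(6.9 * RATE))  # cutting ~0.23 s/side would be fine...
        out = pp.clip_edges(x, RATE)
        assert len(out) <= len(x)
        short = np.ones(int(5.4 * RATE) * 0 + 2100)  # 1.05 s
        assert len(pp.clip_edges(short, RATE)) == len(short)


class TestClipByEnvelope:
    def test_constant_envelope_keeps_all(self):
        x = tone(50, dur=2.0)
        assert len(pp.clip_by_envelope(x, RATE)) == len(x)

    def test_burst_excluded_matches_threshold_scan(self):
        """Brute-force threshold + bridge + run-length scan as oracle."""
        from scipy.signal import hilbert
        x = 0.1 * np.sin(2 * np.pi * 60 * np.arange(32000) / RATE)
        burst = np.arange(1000)  # 0.5 s sustained disturbance
        x[15000:16000] += 5.0 * np.sin(2 * np.pi * 80 * burst / RATE)
        out = pp.clip_by_envelope(x, RATE, g_th=2.7)
        env = np.abs(hilbert(x))
        keep = list(env < env.mean() + 2.7 * env.std())
        # oracle: bridge violations shorter than 0.25 s, then longest run
        bridge = int(0.25 * RATE)
        i = 0
        while i < len(keep):
            if not keep[i]:
                j = i
                while j < len(keep) and not keep[j]:
                    j += 1
                if j - i < bridge:
                    for k in range(i, j):
                        keep[k] = True
                i = j
            else:
                i += 1
        runs, start = [], None
        for i, k in enumerate(keep + [False]):
            if k and start is None:
                start = i
            elif not k and start is not None:
                runs.append((start, i))
                start = None
        lo, hi = max(runs, key=lambda r: r[1] - r[0])
        assert np.array_equal(out, x[lo:hi])
        assert hi <= 15100 or lo >= 15900  # burst excluded

    def test_infinite_gain_keeps_all(self, rng):
        x = rng.standard_normal(4000)
        assert len(pp.clip_by_envelope(x, RATE, g_th=np.inf)) == len(x)


def test_pipeline_deterministic_and_contiguous(clean_recording):
    """The feature chain is deterministic and returns an unmodified sub-interval."""
    x1, off1 = pp.feature_preprocess(clean_recording.samples, RATE)
    x1b, off1b = pp.feature_preprocess(clean_recording.samples, RATE)
    assert off1 == off1b and np.array_equal(x1, x1b)
    ref = pp.despike(clean_recording.samples, RATE)
    assert np.allclose(x1, ref[off1:off1 + len(x1)], atol=1e-9)
    # the envelope-clip stage alone is a fixed point on its own output
    y = pp.clip_by_envelope(x1, RATE)
    assert len(y) > 0.8 * len(x1)


def test_quality_flags_clean_on_defect_free_recording(clean_recording):
    report = pp.assess_quality(clean_recording.samples, RATE)
    assert report.usable_mask.all()
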