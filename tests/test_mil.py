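"""MIL U-Net: pooling oracle, postprocessing, precision counting, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartmil import SimConfig, synth_recording
from heartmil.mil import (MILBag, MILUNet, MILUNetDetector, NO_ACTIVATION,
                          MurmurSegment, bag_probability, murmurness,
                          phase_precision, postprocess, pseudo_precision,
                          softmax_pool)
from heartmil.segmentation import Interval, PhaseSegmentation

RATE = 2000.0


def eq1_oracle(p):
    """Direct evaluation of the softmax-pooling definition."""
    p = np.asarray(p, dtype=np.float64)
    return float(np.sum(p * np.exp(p)) / np.sum(np.exp(p)))


class TestSoftmaxPool:
    def test_single_instance_and_uniform(self):
        assert softmax_pool([0.37]) == pytest.approx(0.37)
        assert softmax_pool([0.6] * 50) == pytest.approx(0.6)

    def test_two_instance_closed_form(self):
        expected = (0.1 * np.exp(0.1) + 0.9 * np.exp(0.9)) / \
            (np.exp(0.1) + np.exp(0.9))
        assert softmax_pool([0.1, 0.9]) == pytest.approx(expected, abs=1e-12)
        assert softmax_pool([0.1, 0.9]) == pytest.approx(0.652, abs=5e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            softmax_pool([])
        with pytest.raises(ValueError):
            softmax_pool([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=64))
    def test_bounds_and_oracle(self, probs):
        pooled = softmax_pool(probs)
        assert pooled == pytest.approx(eq1_oracle(probs), abs=1e-12)
        assert np.mean(probs) - 1e-12 <= pooled <= max(probs) + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=32),
           st.integers(0, 31), st.floats(0.0, 1.0))
    def test_permutation_invariance_and_monotonicity(self, probs, idx, newval):
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(probs))
        assert softmax_pool(shuffled) == pytest.approx(softmax_pool(probs),
                                                       abs=1e-12)
        i = idx % len(probs)
        raised = list(probs)
        raised[i] = max(raised[i], newval)
        assert softmax_pool(raised) >= softmax_pool(probs) - 1e-12


class TestUNetModel:
    @pytest.mark.parametrize("length", [2 ** 12, 2 ** 14])
    def test_output_length_equals_input_length(self, length, rng):
        model = MILUNet(base_channels=2, seed=0)
        x = rng.standard_normal((1, 1, length)).astype(np.float32)
        assert model.forward(x, training=False).shape == (1, length)

    def test_constant_input_gives_spatially_constant_output(self):
        """Translation invariance of convolutions on constant input."""
        model = MILUNet(base_channels=2, seed=1)
        x = np.zeros((1, 1, 2 ** 10), dtype=np.float32)
        out = model.forward(x, training=False)[0]
        interior = out[64:-64]  # away from zero-padding boundary effects
        assert np.max(interior) - np.min(interior) < 1e-5

    def test_indivisible_length_rejected(self):
        model = MILUNet(base_channels=2)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 1000), dtype=np.float32))

    def test_murmurness_bounded_and_length_preserving(self, rng):
        model = MILUNet(base_channels=2, seed=2)
        x = rng.standard_normal(5000)
        trace = murmurness(model, x)
        assert trace.shape == (5000,)
        assert trace.min() >= 0.0 and trace.max() <= 1.0


def triangle_trace(n, center, width, peak):
    t = np.zeros(n)
    for i in range(max(0, center - width), min(n, center + width + 1)):
        t[i] = peak * (1 - abs(i - center) / width)
    return t


class TestPostprocess:
    def test_all_zero_trace_gives_no_segments(self):
        assert postprocess(np.zeros(4000), RATE) == []

    def test_sixty_ms_merge_rule(self):
        """Peaks 30 ms apart merge into one segment; 100 ms apart stay two."""
        n = 4000
        near = triangle_trace(n, 1000, 40, 0.95) + triangle_trace(n, 1060, 40, 0.9)
        segs = postprocess(near, RATE)
        assert len(segs) == 1
        far = triangle_trace(n, 1000, 40, 0.95) + triangle_trace(n, 1200, 40, 0.9)
        assert len(postprocess(far, RATE)) == 2

    def test_triangular_pulse_single_segment_contains_apex(self):
        trace = triangle_trace(4000, 700, 100, 0.9)
        segs = postprocess(trace, RATE)
        assert len(segs) == 1
        assert segs[0].start <= 700 < segs[0].end
        assert segs[0].peak == pytest.approx(0.9)

    def test_threshold_honoured_exactly(self):
        trace = triangle_trace(4000, 700, 100, 0.59)
        assert postprocess(trace, RATE, threshold=0.6) == []
        trace2 = triangle_trace(4000, 700, 100, 0.75)
        segs = postprocess(trace2, RATE, threshold=0.6)
        assert len(segs) == 1

    def test_matches_brute_force_on_random_traces(self, rng):
        """Independent oracle: direct peak scan + prominence + exhaustive merge."""
        from scipy.ndimage import uniform_filter1d

        def oracle(t, rate, thr=0.6, merge_ms=60.0, prom=0.1):
            peaks = []
            for i in range(1, len(t) - 1):
                if t[i] > t[i - 1] and t[i] > t[i + 1] and t[i] >= thr:
                    # prominence: min valley to the nearer higher ground
                    left = t[:i][::-1]
                    right = t[i + 1:]
                    lmin, lbase = t[i], t[i]
                    for v in left:
                        if v > t[i]:
                            break
                        lmin = min(lmin, v)
                    lbase = lmin
                    rmin = t[i]
                    for v in right:
                        if v > t[i]:
                            break
                        rmin = min(rmin, v)
                    if t[i] - max(lbase, rmin) >= prom:
                        peaks.append(i)
            if not peaks:
                return []
            gap = merge_ms / 1000 * rate
            groups = [[peaks[0]]]
            for p in peaks[1:]:
                (groups[-1].append(p) if p - groups[-1][-1] <= gap
                 else groups.append([p]))
            out = []
            for g in groups:
                lo = g[0]
                while lo > 0 and t[lo - 1] >= thr:
                    lo -= 1
                hi = g[-1]
                while hi < len(t) - 1 and t[hi + 1] >= thr:
                    hi += 1
                out.append((lo, hi + 1))
            return out

        for trial in range(10):
            raw = rng.standard_normal(5000).cumsum()
            raw = uniform_filter1d(raw, 25)
            t = (raw - raw.min()) / (raw.max() - raw.min())
            got = [(s.start, s.end) for s in postprocess(t, RATE)]
            assert got == oracle(t, RATE)


def _toy_segmentation():
    ivs = []
    t = 0
    for _ in range(4):
        for lab, ln in (("S1", 100), ("systole", 300), ("S2", 80),
                        ("diastole", 400)):
            ivs.append(Interval(t, t + ln, lab))
            t += ln
    return PhaseSegmentation(ivs)


class TestPhasePrecision:
    def test_all_in_systole(self):
        seg = _toy_segmentation()
        segs = [MurmurSegment(150, 250, 0.9), MurmurSegment(1050, 1150, 0.8),
                MurmurSegment(1950, 2000, 0.7), MurmurSegment(2800, 2900, 0.9)]
        assert phase_precision(segs, seg, "systolic") == 1.0

    def test_no_activation_sentinel(self):
        assert phase_precision([], _toy_segmentation(), "systolic") == NO_ACTIVATION

    def test_three_of_four(self):
        seg = _toy_segmentation()
        segs = [MurmurSegment(150, 250, 0.9), MurmurSegment(1050, 1150, 0.8),
                MurmurSegment(1950, 2000, 0.7),
                MurmurSegment(500, 600, 0.9)]  # diastole only
        assert phase_precision(segs, seg, "systolic") == pytest.approx(0.75)

    def test_pseudo_precision_counts_systole(self):
        seg = _toy_segmentation()
        assert pseudo_precision([MurmurSegment(500, 600, 0.9)], seg) == 0.0
        half = [MurmurSegment(500, 600, 0.9), MurmurSegment(150, 200, 0.9)]
        assert pseudo_precision(half, seg) == pytest.approx(0.5)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            phase_precision([], _toy_segmentation(), "mid-systolic")


class TestBag:
    def test_label_validation(self):
        with pytest.raises(ValueError):
            MILBag(np.zeros(4), 2)


def _tiny_recordings(n_per_class, seed0, duration=2.048):
    recs = []
    for i in range(n_per_class):
        recs.append(synth_recording(SimConfig(duration=duration, heart_rate=120.0,
                                              murmur_present=True, murmur_snr=9.0,
                                              seed=seed0 + i)))
        recs.append(synth_recording(SimConfig(duration=duration, heart_rate=120.0,
                                              seed=seed0 + 500 + i)))
    return recs


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self):
        recs = _tiny_recordings(3, seed0=0)
        det = MILUNetDetector(base_channels=2, epochs=0, batch_size=4,
                              fixed_length=2 ** 12, random_state=0)
        ref = MILUNet(base_channels=2, depth=5, kernel_size=5,
                      seed=int(np.random.default_rng(0).integers(2 ** 31)))
        det.fit(recs)
        for a, b in zip(det.model_.state_dict(), ref.state_dict()):
            assert np.array_equal(a, b)

    def test_loss_decreases_and_seed_reproducible(self):
        recs = _tiny_recordings(8, seed0=10)
        kw = dict(base_channels=2, epochs=8, batch_size=8,
                  fixed_length=2 ** 12, random_state=3)
        det = MILUNetDetector(**kw).fit(recs)
        assert det.history_["train_loss"][-1] < det.history_["train_loss"][0]
        det2 = MILUNetDetector(**kw).fit(recs)
        assert det.history_ == det2.history_

    def test_single_class_rejected(self):
        recs = [synth_recording(SimConfig(duration=2.048, heart_rate=120.0,
                                          seed=s)) for s in range(4)]
        with pytest.raises(ValueError):
            MILUNetDetector(epochs=1, fixed_length=2 ** 12).fit(recs)
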