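"""Signal conditioning for phonocardiograms.

Two chains are provided.  The *model* chain (resample to 2 kHz, quality
assessment, 10th-order Butterworth band-pass 10-800 Hz, best-quality segment
selection, minimum-cycle rule) prepares recordings for the neural models.
The *feature* chain (despiking, duration-dependent edge clipping, Hilbert-
envelope clipping) additionally removes transients that distort handcrafted
features.

Quality criteria follow the classic two-test scheme: a window is *saturated*
when the extremes of its amplitude histogram are over-represented, and
*noisy* when the Hilbert-envelope energy of the 100-250 Hz band exceeds that
of the 15-90 Hz band (heart sounds live mostly below 100 Hz, broadband noise
does not).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .segmentation import PhaseSegmentation, cycles


class RecordingRejected(ValueError):
    """Raised when a recording fails the usability rules."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: float = 2000.0
    band: tuple[float, float] = (10.0, 800.0)
    filter_order: int = 10
    envelope_gain: float = 2.7          # g_th of the envelope-clipping rule
    min_cycles: int = 3
    quality_window_s: float = 1.0
    saturation_edge: float = 0.02       # top/bottom amplitude range fraction
    saturation_fraction: float = 0.30   # joint mass above which a window saturates
    noise_bands: tuple[tuple[float, float], tuple[float, float]] = (
        (100.0, 250.0), (15.0, 90.0))

    def __post_init__(self):
        lo, hi = self.band
        if not 0 < lo < hi < self.target_rate / 2:
            raise ValueError("band must lie inside (0, Nyquist)")
        if self.envelope_gain <= 0:
            raise ValueError("envelope_gain must be positive")


@dataclass
class QualityReport:
    saturation_flags: np.ndarray        # per window
    noise_flags: np.ndarray             # per window
    usable_mask: np.ndarray             # per sample
    window_length: int
    usable_cycle_count: int | None = None

    def to_json(self) -> str:
        return json.dumps({
            "saturation_flags": self.saturation_flags.astype(int).tolist(),
            "noise_flags": self.noise_flags.astype(int).tolist(),
            "window_length": int(self.window_length),
            "usable_fraction": float(np.mean(self.usable_mask)),
            "usable_cycle_count": self.usable_cycle_count,
        })


def resample(samples: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Linear-interpolation resampling; output length = round(n * out / in)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot resample an empty signal")
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("sampling rates must be positive")
    if rate_in == rate_out:
        return x.copy()
    n_out = int(round(x.size * rate_out / rate_in))
    t_out = np.arange(n_out) / rate_out
    t_in = np.arange(x.size) / rate_in
    return np.interp(t_out, t_in, x)


def _band_sos(band: tuple[float, float], rate: float, order: int = 4):
    # scipy doubles the order for band-pass designs
    return sps.butter(max(order // 2, 1), band, btype="bandpass",
                      fs=rate, output="sos")


def band_envelope(samples: np.ndarray, rate: float,
                  band: tuple[float, float]) -> np.ndarray:
    """Hilbert envelope of the band-passed signal (zero-phase filtering)."""
    lo, hi = band
    if not 0 < lo < hi < rate / 2:
        raise ValueError(f"band {band} outside (0, Nyquist)")
    x = np.asarray(samples, dtype=np.float64)
    filtered = sps.sosfiltfilt(_band_sos(band, rate), x)
    return np.abs(sps.hilbert(filtered))


def assess_quality(samples: np.ndarray, rate: float,
                   config: PreprocessConfig | None = None) -> QualityReport:
    """Window-wise saturation and noise flags plus a per-sample usable mask."""
    config = config or PreprocessConfig()
    x = np.asarray(samples, dtype=np.float64)
    win = max(1, int(round(config.quality_window_s * rate)))
    # trailing partial windows merge into the last full window
    n_win = max(1, x.size // win)
    bounds = [(w * win, (w + 1) * win if w < n_win - 1 else x.size)
              for w in range(n_win)]
    hi_env = band_envelope(x, rate, config.noise_bands[0]) if x.size > 18 else None
    lo_env = band_envelope(x, rate, config.noise_bands[1]) if x.size > 18 else None
    sat = np.zeros(n_win, dtype=bool)
    noisy = np.zeros(n_win, dtype=bool)
    for w, (lo_b, hi_b) in enumerate(bounds):
        seg = x[lo_b:hi_b]
        lo, hi = float(seg.min()), float(seg.max())
        rng = hi - lo
        if rng > 1e-12:
            edge = config.saturation_edge * rng
            frac = np.mean((seg >= hi - edge) | (seg <= lo + edge))
            sat[w] = frac > config.saturation_fraction
        if hi_env is not None:
            e_hi = float(np.sum(hi_env[w * win:(w + 1) * win] ** 2))
            e_lo = float(np.sum(lo_env[w * win:(w + 1) * win] ** 2))
            noisy[w] = e_hi > e_lo  # strict: all-zero windows count as clean
    ok = ~sat & ~noisy
    per_sample = np.empty(x.size, dtype=bool)
    for w, (lo_b, hi_b) in enumerate(bounds):
        per_sample[lo_b:hi_b] = ok[w]
    return QualityReport(sat, noisy, per_sample, win)


def bandpass(samples: np.ndarray, rate: float,
             config: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase 10th-order Butterworth band-pass (default 10-800 Hz)."""
    config = config or PreprocessConfig()
    lo, hi = config.band
    if hi >= rate / 2:
        raise ValueError("upper band edge must be below Nyquist")
    sos = sps.butter(config.filter_order // 2, (lo, hi), btype="bandpass",
                     fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=np.float64))


def best_segment(samples: np.ndarray, quality: QualityReport,
                 target_length: int) -> tuple[int, int]:
    """Contiguous window maximising the fraction of usable samples.

    Leftmost window on ties; falls back to the signal prefix (with a
    warning) when nothing is usable.
    """
    n = len(samples)
    if target_length > n:
        raise ValueError("target_length exceeds signal length")
    mask = quality.usable_mask.astype(np.int64)
    if not mask.any():
        warnings.warn("no usable samples; falling back to signal prefix")
        return 0, target_length
    csum = np.concatenate([[0], np.cumsum(mask)])
    counts = csum[target_length:] - csum[:-target_length] if target_length < n \
        else np.array([csum[-1]])
    start = int(np.argmax(counts))
    return start, start + target_length


def count_usable_cycles(segmentation: PhaseSegmentation,
                        quality: QualityReport) -> int:
    """Number of complete S1->diastole cycles fully inside the usable mask."""
    mask = quality.usable_mask
    csum = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
    count = 0
    for s1, _sys, _s2, dias in cycles(segmentation):
        start, end = s1.start, dias.end
        if end > len(mask):
            continue
        if csum[end] - csum[start] == end - start:
            count += 1
    return count


def require_min_cycles(segmentation: PhaseSegmentation, quality: QualityReport,
                       min_cycles: int = 3) -> int:
    n = count_usable_cycles(segmentation, quality)
    if n < min_cycles:
        raise RecordingRejected(
            f"only {n} usable heart cycles (minimum {min_cycles})")
    return n


def despike(samples: np.ndarray, rate: float, window_s: float = 0.5,
            factor: float = 3.0, max_iter: int = 100) -> np.ndarray:
    """Schmidt-style despiking.

    The signal is cut into ``window_s`` windows; while some window's maximum
    absolute amplitude exceeds ``factor`` times the median of window maxima,
    the spike in the worst window is located at the maximum slope of the
    absolute signal, its above-median run is removed and bridged by linear
    interpolation.
    """
    x = np.asarray(samples, dtype=np.float64).copy()
    if x.size == 0:
        return x
    win = max(2, int(round(window_s * rate)))
    n_win = max(1, x.size // win)
    for _ in range(max_iter):
        maxima = np.array([np.max(np.abs(x[w * win:(w + 1) * win]))
                           for w in range(n_win)])
        med = float(np.median(maxima))
        if med <= 0 or np.max(maxima) <= factor * med:
            break
        w = int(np.argmax(maxima))
        lo_w, hi_w = w * win, min((w + 1) * win, x.size)
        seg_abs = np.abs(x[lo_w:hi_w])
        slopes = np.abs(np.diff(seg_abs))
        center = lo_w + (int(np.argmax(slopes)) if slopes.size else 0)
        run_lo = center
        while run_lo > lo_w and np.abs(x[run_lo - 1]) > med:
            run_lo -= 1
        run_hi = center
        while run_hi < hi_w - 1 and np.abs(x[run_hi + 1]) > med:
            run_hi += 1
        a = x[run_lo - 1] if run_lo > 0 else 0.0
        b = x[run_hi + 1] if run_hi < x.size - 1 else 0.0
        x[run_lo:run_hi + 1] = np.linspace(a, b, run_hi - run_lo + 3)[1:-1]
    return x


def edge_clip_seconds(duration_s: float) -> float:
    """Per-end cut length: 0 s at a 5 s recording, 3 s at 30 s, linear between."""
    return float(np.clip(3.0 * (duration_s - 5.0) / 25.0, 0.0, 3.0))


def clip_edges_slice(n_samples: int, rate: float) -> slice:
    cut = int(round(edge_clip_seconds(n_samples / rate) * rate))
    if n_samples - 2 * cut < rate:  # would leave less than 1 s
        warnings.warn("edge clipping would leave <1 s; keeping full signal")
        return slice(0, n_samples)
    return slice(cut, n_samples - cut)


def clip_edges(samples: np.ndarray, rate: float) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float64)
    return x[clip_edges_slice(x.size, rate)]


def clip_by_envelope_slice(samples: np.ndarray, rate: float,
                           g_th: float = 2.7,
                           bridge_s: float = 0.25) -> slice:
    """Longest run where the Hilbert envelope stays below mean + g_th * std.

    Threshold violations shorter than ``bridge_s`` do not break a run: the
    rule targets sustained disturbances, and transient heart sounds (S1/S2
    last well under 250 ms) must not fragment the kept signal.  A
    zero-variance envelope keeps the whole signal (a strict inequality
    would otherwise keep nothing).  Runs longer than 15 s are additionally
    trimmed by 5 s at each end, as the boundary samples sit close to the
    threshold.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    env = np.abs(sps.hilbert(x))
    std = float(np.std(env))
    if std < 1e-12 * max(float(np.mean(env)), 1e-30) or std == 0.0:
        return slice(0, x.size)
    keep = env < float(np.mean(env)) + g_th * std
    if not keep.any():
        warnings.warn("no sample satisfies the envelope criterion; keeping all")
        return slice(0, x.size)
    # bridge short violations (transient sounds), then take the longest run
    bridge = int(round(bridge_s * rate))
    padded = np.concatenate([[True], keep, [True]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for v_lo, v_hi in zip(edges[0::2], edges[1::2]):  # False runs
        if v_hi - v_lo < bridge:
            keep[v_lo:v_hi] = True
    padded = np.concatenate([[False], keep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    best = int(np.argmax(ends - starts))
    lo, hi = int(starts[best]), int(ends[best])
    if hi - lo > 15 * rate:
        trim = int(5 * rate)
        lo, hi = lo + trim, hi - trim
    return slice(lo, hi)


def clip_by_envelope(samples: np.ndarray, rate: float,
                     g_th: float = 2.7) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float64)
    return x[clip_by_envelope_slice(x, rate, g_th)]


def feature_preprocess(samples: np.ndarray, rate: float,
                       g_th: float = 2.7) -> tuple[np.ndarray, int]:
    """Feature-chain preprocessing: despike, clip edges, clip by envelope.

    Returns the conditioned samples together with the offset of their first
    sample in the input, so reference segmentations can be re-aligned.
    """
    x = despike(samples, rate)
    s1 = clip_edges_slice(x.size, rate)
    x = x[s1]
    s2 = clip_by_envelope_slice(x, rate, g_th)
    return x[s2], s1.start + s2.start
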