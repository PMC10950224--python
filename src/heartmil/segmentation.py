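"""Heart-phase segmentation: reference TSV I/O and an envelope-based segmenter.

A phonocardiogram cycle consists of the first heart sound (S1), systole, the
second heart sound (S2) and diastole.  Downstream feature extraction and the
explainability evaluation only depend on the :class:`PhaseSegmentation`
contract: an ordered list of half-open, 0-based sample intervals labelled
with one of the four phases (or ``unlabeled`` for gaps).

Two sources of segmentations are supported:

* reference TSV files in the CirCor DigiScope dialect (three tab-separated
  columns: start seconds, end seconds, state code 1=S1, 2=systole, 3=S2,
  4=diastole, 0=unlabeled), preferred whenever available;
* :func:`segment_phases`, a light-weight segmenter that detects S1/S2 as
  peaks of a smoothed homomorphic envelope and resolves the S1/S2
  alternation with the physiological rule that systole is shorter than
  diastole.  It replaces heavier HSMM-based segmenters for signals where no
  reference annotation exists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

S1, SYSTOLE, S2, DIASTOLE, UNLABELED = "S1", "systole", "S2", "diastole", "unlabeled"
PHASE_LABELS = (S1, SYSTOLE, S2, DIASTOLE)
_CODE_TO_LABEL = {0: UNLABELED, 1: S1, 2: SYSTOLE, 3: S2, 4: DIASTOLE}
_LABEL_TO_CODE = {v: k for k, v in _CODE_TO_LABEL.items()}
_CYCLE_ORDER = (S1, SYSTOLE, S2, DIASTOLE)


@dataclass(frozen=True)
class Interval:
    """Half-open sample interval ``[start, end)`` with a phase label."""

    start: int
    end: int
    label: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval ({self.start}, {self.end})")
        if self.label not in _LABEL_TO_CODE:
            raise ValueError(f"unknown phase label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class PhaseSegmentation:
    """Sorted, non-overlapping phase intervals over a signal."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        prev_end = -1
        for i, iv in enumerate(self.intervals):
            if iv.start < prev_end:
                raise ValueError(f"interval {i} overlaps or is unsorted")
            prev_end = iv.end

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def labelled(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    def to_json(self) -> str:
        return json.dumps([[iv.start, iv.end, iv.label] for iv in self.intervals])

    @classmethod
    def from_json(cls, text: str) -> "PhaseSegmentation":
        return cls([Interval(s, e, lab) for s, e, lab in json.loads(text)])


def read_segmentation_tsv(path, rate: float) -> PhaseSegmentation:
    """Read a CirCor-style three-column segmentation TSV.

    Seconds are converted to samples with floor for starts and ceil for
    ends, so annotated intervals never shrink.  Overlapping or unsorted
    rows are rejected with the offending row number.
    """
    intervals: list[Interval] = []
    prev_end_s = -math.inf
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"row {row_no}: expected 3 columns, got {len(parts)}")
            start_s, end_s, code = float(parts[0]), float(parts[1]), int(float(parts[2]))
            if code not in _CODE_TO_LABEL:
                raise ValueError(f"row {row_no}: unknown state code {code}")
            if start_s < prev_end_s - 1e-12:
                raise ValueError(f"row {row_no}: rows overlap or are out of order")
            prev_end_s = end_s
            start = math.floor(start_s * rate)
            end = math.ceil(end_s * rate)
            # floor/ceil on adjacent boundaries may collide by one sample
            if intervals and start < intervals[-1].end:
                start = intervals[-1].end
            if end > start:
                intervals.append(Interval(start, end, _CODE_TO_LABEL[code]))
    return PhaseSegmentation(intervals)


def write_segmentation_tsv(path, segmentation: PhaseSegmentation, rate: float) -> None:
    with open(path, "w") as fh:
        for iv in segmentation:
            fh.write(f"{iv.start / rate:.6f}\t{iv.end / rate:.6f}\t"
                     f"{_LABEL_TO_CODE[iv.label]}\n")


def homomorphic_envelope(samples: np.ndarray, rate: float,
                         smooth_ms: float = 50.0) -> np.ndarray:
    """Smoothed homomorphic (log-domain low-passed) amplitude envelope."""
    x = np.asarray(samples, dtype=np.float64)
    analytic = sps.hilbert(x)
    env = np.abs(analytic)
    log_env = np.log(env + 1e-12)
    # low-pass in the log domain, then exponentiate back
    n = max(3, int(round(smooth_ms / 1000.0 * rate)) | 1)
    kernel = np.hanning(n)
    kernel /= kernel.sum()
    smoothed = np.convolve(log_env, kernel, mode="same")
    return np.exp(smoothed)


def _sound_extent(env: np.ndarray, peak: int, rate: float,
                  max_ms: float = 120.0, min_ms: float = 60.0) -> tuple[int, int]:
    """Extend from an envelope peak to half height, clamped to 60-120 ms."""
    half = env[peak] / 2.0
    max_half = int(round(max_ms / 2000.0 * rate))
    lo = peak
    while lo > 0 and peak - lo < max_half and env[lo - 1] > half:
        lo -= 1
    hi = peak
    n = len(env)
    while hi < n - 1 and hi - peak < max_half and env[hi + 1] > half:
        hi += 1
    min_half = int(round(min_ms / 2000.0 * rate))
    lo = min(lo, peak - min_half)
    hi = max(hi, peak + min_half)
    return max(lo, 0), min(hi + 1, n)


def segment_phases(samples: np.ndarray, rate: float) -> PhaseSegmentation:
    """Envelope-peak segmentation of a preprocessed phonocardiogram.

    S1 and S2 candidates are local maxima of the homomorphic envelope at
    least 150 ms apart; alternation is resolved by assigning the shorter of
    the two alternating gap classes to systole (S1->S2).  Raises
    ``ValueError`` when fewer than three complete cycles are detected or
    the peak train shows no usable periodicity.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < int(rate):
        raise ValueError("signal too short to segment")
    env = homomorphic_envelope(x, rate)
    min_dist = int(0.15 * rate)
    peaks, _ = sps.find_peaks(env, distance=min_dist,
                              height=0.2 * float(np.max(env)))
    if len(peaks) < 7:  # 3 cycles need >= 7 alternating sounds
        raise ValueError("fewer than three heart cycles detected")
    # transient sounds must stand out of the envelope background
    if float(np.mean(env[peaks])) < 1.4 * float(np.median(env)):
        raise ValueError("no heart-sound-like transients found")
    gaps = np.diff(peaks)
    # alternating gap classes: even-indexed vs odd-indexed gaps
    even_mean = float(np.mean(gaps[0::2]))
    odd_mean = float(np.mean(gaps[1::2]))
    lo_m, hi_m = min(even_mean, odd_mean), max(even_mean, odd_mean)
    # periodicity sanity: each gap class must be reasonably tight
    for cls in (gaps[0::2], gaps[1::2]):
        if len(cls) >= 2 and np.std(cls) > 0.35 * np.mean(cls):
            raise ValueError("no consistent cardiac periodicity found")
    if hi_m >= 1.15 * lo_m:
        # systole (S1->S2) is the shorter gap
        first_is_s1 = even_mean < odd_mean
    else:
        # gaps too similar (fast heart rates): S1 is the louder sound
        h_even = float(np.mean(env[peaks[0::2]]))
        h_odd = float(np.mean(env[peaks[1::2]]))
        if max(h_even, h_odd) < 1.05 * min(h_even, h_odd):
            raise ValueError("could not resolve S1/S2 alternation")
        first_is_s1 = h_even > h_odd
    intervals: list[Interval] = []
    labels = [S1 if (i % 2 == 0) == first_is_s1 else S2 for i in range(len(peaks))]
    sounds = [_sound_extent(env, p, rate) for p in peaks]
    if sounds[0][0] > 0:
        intervals.append(Interval(0, sounds[0][0], UNLABELED))
    for i, ((lo, hi), lab) in enumerate(zip(sounds, labels)):
        lo = max(lo, intervals[-1].end if intervals else 0)
        if hi <= lo:
            continue
        intervals.append(Interval(lo, hi, lab))
        if i + 1 < len(sounds):
            nxt = max(sounds[i + 1][0], hi)
            if nxt > hi:
                phase = SYSTOLE if lab == S1 else DIASTOLE
                intervals.append(Interval(hi, nxt, phase))
    if sounds[-1][1] < x.size:
        intervals.append(Interval(sounds[-1][1], x.size, UNLABELED))
    seg = PhaseSegmentation(intervals)
    if len(cycles(seg)) < 3:
        raise ValueError("fewer than three complete heart cycles segmented")
    return seg


def cycles(segmentation: PhaseSegmentation) -> list[tuple[Interval, Interval, Interval, Interval]]:
    """Complete S1->systole->S2->diastole runs, in temporal order."""
    labelled = [iv for iv in segmentation if iv.label != UNLABELED]
    out = []
    i = 0
    while i + 4 <= len(labelled):
        window = labelled[i:i + 4]
        if tuple(iv.label for iv in window) == _CYCLE_ORDER:
            out.append(tuple(window))
            i += 4
        else:
            i += 1
    return out
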