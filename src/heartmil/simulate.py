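"""Synthetic phonocardiogram generator with exact ground truth.

Produces recordings that are statistically realistic enough to exercise the
whole murmur-detection stack: periodic S1/S2 valve-closure transients
(decaying band-limited chirps, S2 slightly higher pitched), optional
systolic and/or diastolic murmurs synthesised as band-limited noise shaped
by one of the four classic murmur envelopes (diamond, plateau, crescendo,
decrescendo), plus additive noise, spike artefacts and saturation defects.
Unlike real data, every recording carries an exact phase segmentation and
exact murmur intervals, which downstream modules use as strong labels.

Patient-level cohorts mirror the auscultation convention of up to four
stethoscope locations per patient with consistent demographics, a
three-class murmur label (Present / Unknown / Absent) and a binary clinical
outcome.  "Unknown" is emulated as a barely audible murmur buried in heavy
noise, giving the three-class tasks a non-degenerate middle class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import shape_template
from .segmentation import (DIASTOLE, S1, S2, SYSTOLE, UNLABELED, Interval,
                           PhaseSegmentation)

LOCATIONS = ("AV", "PV", "TV", "MV", "other")
MURMUR_PHASES = ("systolic", "diastolic", "both")
MURMUR_SHAPES = ("diamond", "plateau", "crescendo", "decrescendo")
MURMUR_LABELS = ("Present", "Unknown", "Absent")
OUTCOME_LABELS = ("Normal", "Abnormal")


@dataclass(frozen=True)
class SimConfig:
    sampling_rate: float = 2000.0
    duration: float = 8.192           # seconds; 2^14 samples at 2 kHz
    heart_rate: float = 80.0          # beats per minute
    hr_jitter: float = 0.02           # fractional cycle-length jitter
    murmur_present: bool = False
    murmur_phase: str = "systolic"
    murmur_shape: str = "diamond"
    murmur_band: tuple[float, float] = (200.0, 450.0)
    murmur_snr: float = 6.0           # dB, murmur envelope peak vs S1 peak
    noise_level: float = 0.02         # additive noise, relative to S1 peak
    spike_rate: float = 0.0           # artefact spikes per second
    saturation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.murmur_band
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ValueError("murmur_band must satisfy 0 < low < high < Nyquist")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 40 <= self.heart_rate <= 220:
            raise ValueError("heart_rate must be in [40, 220] bpm")
        if self.murmur_phase not in MURMUR_PHASES:
            raise ValueError(f"murmur_phase must be one of {MURMUR_PHASES}")
        if self.murmur_shape not in MURMUR_SHAPES:
            raise ValueError(f"murmur_shape must be one of {MURMUR_SHAPES}")


@dataclass(frozen=True)
class DemographicRecord:
    age_months: float | None = None
    sex: str | None = None            # "female" / "male"
    weight_kg: float | None = None
    height_cm: float | None = None

    def __post_init__(self):
        for name in ("age_months", "weight_kg", "height_cm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticRecording:
    samples: np.ndarray
    sampling_rate: float
    segmentation: PhaseSegmentation
    murmur_intervals: list[tuple[int, int, str]]
    location: str = "AV"
    demographics: DemographicRecord = field(default_factory=DemographicRecord)
    murmur_label: str = "Absent"
    outcome_label: str = "Normal"
    patient_id: str = "0"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class Patient:
    patient_id: str
    demographics: DemographicRecord
    murmur_label: str
    outcome_label: str
    recordings: list[SyntheticRecording]


def _decaying_chirp(rng: np.random.Generator, rate: float, dur_s: float,
                    f_hi: float, f_lo: float, amp: float) -> np.ndarray:
    n = max(int(round(dur_s * rate)), 8)
    t = np.arange(n) / rate
    freq = f_hi + (f_lo - f_hi) * t / t[-1]
    phase = 2 * np.pi * np.cumsum(freq) / rate + rng.uniform(0, 2 * np.pi)
    env = np.exp(-t / (dur_s / 3.0))
    # short attack so the onset is not a discontinuity
    attack = min(n // 8 + 1, n)
    env[:attack] *= np.linspace(0.0, 1.0, attack)
    return amp * env * np.sin(phase)


def _sound_durations(period_s: float) -> tuple[float, float]:
    scale = min(1.0, period_s / 0.5)
    return max(0.05, 0.10 * scale), max(0.04, 0.08 * scale)


def synth_recording(config: SimConfig,
                    demographics: DemographicRecord | None = None,
                    location: str = "AV") -> SyntheticRecording:
    """Generate one annotated recording; identical seeds are bit-identical."""
    rate = config.sampling_rate
    if config.duration * config.heart_rate / 60.0 < 3.0:
        raise ValueError("duration too short for three heart cycles")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * rate))
    x = np.zeros(n)

    # band-limited noise carrier for murmurs, shared across cycles
    sos = sps.butter(2, config.murmur_band, btype="bandpass", fs=rate,
                     output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal(n))
    carrier /= max(float(np.sqrt(np.mean(carrier ** 2))), 1e-12)
    murmur_amp = 10.0 ** (config.murmur_snr / 20.0)

    intervals: list[Interval] = []
    murmur_intervals: list[tuple[int, int, str]] = []
    t = 0.0
    while True:
        period = (60.0 / config.heart_rate) * (
            1.0 + rng.uniform(-config.hr_jitter, config.hr_jitter))
        if t + period > config.duration:
            break
        s1_d, s2_d = _sound_durations(period)
        sys_d = 0.3 * period
        bounds_s = np.array([t, t + s1_d, t + s1_d + sys_d,
                             t + s1_d + sys_d + s2_d, t + period])
        b = np.round(bounds_s * rate).astype(int)
        b = np.minimum(b, n)
        if np.any(np.diff(b) <= 0):
            break
        for (lo, hi), lab in zip(zip(b[:-1], b[1:]), (S1, SYSTOLE, S2, DIASTOLE)):
            intervals.append(Interval(int(lo), int(hi), lab))
        s1_wave = _decaying_chirp(rng, rate, s1_d, 60.0, 35.0, 1.0)
        x[b[0]:b[0] + len(s1_wave)][:n - b[0]] += s1_wave[:n - b[0]]
        s2_wave = _decaying_chirp(rng, rate, s2_d, 85.0, 50.0, 0.8)
        x[b[2]:b[2] + len(s2_wave)][:n - b[2]] += s2_wave[:n - b[2]]
        if config.murmur_present:
            phases = []
            if config.murmur_phase in ("systolic", "both"):
                phases.append((b[1], b[2], "systolic"))
            if config.murmur_phase in ("diastolic", "both"):
                phases.append((b[3], b[4], "diastolic"))
            for lo, hi, tag in phases:
                inset = max(1, int(round(0.05 * (hi - lo))))
                mlo, mhi = int(lo + inset), int(hi - inset)
                if mhi - mlo < 4:
                    continue
                template = shape_template(config.murmur_shape, mhi - mlo)
                x[mlo:mhi] += murmur_amp * template * carrier[mlo:mhi]
                murmur_intervals.append((mlo, mhi, tag))
        t += period
    last = intervals[-1].end if intervals else 0
    if last < n:
        intervals.append(Interval(last, n, UNLABELED))

    if config.noise_level > 0:
        x += config.noise_level * rng.standard_normal(n)
    n_spikes = rng.poisson(config.spike_rate * config.duration)
    for _ in range(n_spikes):
        pos = rng.integers(1, n - 2)
        amp = rng.uniform(3.0, 6.0) * rng.choice([-1.0, 1.0])
        x[pos - 1:pos + 2] += amp * np.array([0.4, 1.0, 0.4])

    x /= max(float(np.max(np.abs(x))), 1e-12)
    if config.saturation_prob > 0 and rng.random() < config.saturation_prob:
        x = np.clip(x, -0.95, 0.95)

    if demographics is None:
        demographics = _random_demographics(rng)
    return SyntheticRecording(
        samples=x,
        sampling_rate=rate,
        segmentation=PhaseSegmentation(intervals),
        murmur_intervals=murmur_intervals,
        location=location,
        demographics=demographics,
        murmur_label="Present" if config.murmur_present else "Absent",
        outcome_label="Abnormal" if config.murmur_present else "Normal",
    )


def _random_demographics(rng: np.random.Generator) -> DemographicRecord:
    age = float(rng.uniform(12.0, 131.0))        # dominant paediatric age group
    height = 75.0 + 0.45 * age + rng.normal(0.0, 3.0)
    weight = 16.0 * (height / 100.0) ** 2 + rng.normal(0.0, 1.0)
    return DemographicRecord(age_months=age,
                             sex="female" if rng.random() < 0.5 else "male",
                             weight_kg=max(weight, 2.0),
                             height_cm=max(height, 40.0))


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distribution for a synthetic patient cohort.

    Class probabilities default to the label frequencies typical of
    paediatric screening data; per-class acoustic conditions control how
    separable the cohort is.
    """

    class_probs: tuple[float, float, float] = (0.19, 0.07, 0.74)  # P / U / A
    heart_rate_range: tuple[float, float] = (70.0, 140.0)
    duration: float = 8.192
    present_snr_range: tuple[float, float] = (6.0, 12.0)
    unknown_snr_range: tuple[float, float] = (-3.0, 0.0)
    unknown_noise_range: tuple[float, float] = (0.2, 0.4)
    absent_noise_range: tuple[float, float] = (0.01, 0.05)
    phase_probs: tuple[float, float, float] = (0.95, 0.027, 0.023)
    outcome_given_class: tuple[float, float, float] = (0.84, 0.63, 0.38)
    max_locations: int = 4

    def __post_init__(self):
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for rng_pair in (self.heart_rate_range, self.present_snr_range,
                         self.unknown_snr_range, self.unknown_noise_range,
                         self.absent_noise_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"degenerate range {rng_pair}")
        if not 1 <= self.max_locations <= 4:
            raise ValueError("max_locations must be in 1..4")


def synth_cohort(n_patients: int, distribution: CohortConfig | None = None,
                 seed: int = 0) -> list[Patient]:
    """Sample a cohort of patients with 1-4 recording locations each."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    dist = distribution or CohortConfig()
    root = np.random.SeedSequence(seed)
    patients = []
    for pid, child in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(child)
        label = MURMUR_LABELS[int(rng.choice(3, p=dist.class_probs))]
        outcome_p = dist.outcome_given_class[MURMUR_LABELS.index(label)]
        outcome = "Abnormal" if rng.random() < outcome_p else "Normal"
        demo = _random_demographics(rng)
        hr = float(rng.uniform(*dist.heart_rate_range))
        phase = MURMUR_PHASES[int(rng.choice(3, p=np.array(dist.phase_probs)
                                             / sum(dist.phase_probs)))]
        shape = MURMUR_SHAPES[int(rng.integers(4))]
        n_loc = int(rng.integers(1, dist.max_locations + 1))
        locs = list(rng.choice(LOCATIONS[:4], size=n_loc, replace=False))
        recordings = []
        for loc in locs:
            if label == "Present":
                cfg = SimConfig(duration=dist.duration, heart_rate=hr,
                                murmur_present=True, murmur_phase=phase,
                                murmur_shape=shape,
                                murmur_snr=float(rng.uniform(*dist.present_snr_range)),
                                noise_level=float(rng.uniform(*dist.absent_noise_range)),
                                seed=int(rng.integers(2 ** 31)))
            elif label == "Unknown":
                cfg = SimConfig(duration=dist.duration, heart_rate=hr,
                                murmur_present=True, murmur_phase=phase,
                                murmur_shape=shape,
                                murmur_snr=float(rng.uniform(*dist.unknown_snr_range)),
                                noise_level=float(rng.uniform(*dist.unknown_noise_range)),
                                seed=int(rng.integers(2 ** 31)))
            else:
                cfg = SimConfig(duration=dist.duration, heart_rate=hr,
                                murmur_present=False,
                                noise_level=float(rng.uniform(*dist.absent_noise_range)),
                                seed=int(rng.integers(2 ** 31)))
            rec = synth_recording(cfg, demographics=demo, location=loc)
            rec.murmur_label = label
            rec.outcome_label = outcome
            rec.patient_id = str(pid)
            recordings.append(rec)
        patients.append(Patient(str(pid), demo, label, outcome, recordings))
    return patients
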