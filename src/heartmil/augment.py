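"""Stochastic waveform augmentations used during model training.

Nine augmentation kinds are supported: scaling, Gaussian noise, drop,
cutout, shift, resampling (linear time-scaling, simulating a different
heart rate), random resampling (smooth random time warp), sine-wave
addition and low-frequency band-pass filtering (0.2-45 Hz).  All except
plain resampling preserve signal length.  ``compose`` applies each
augmentation independently with its configured probability, in fixed
registry order, capped at a maximum number of augmentations per call.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import resample


@dataclass(frozen=True)
class AugmentationPolicy:
    probability: float = 0.3          # same for every augmentation kind
    max_augmentations: int = 3
    scaling_range: tuple[float, float] = (0.6, 1.4)
    gaussian_sigma_range: tuple[float, float] = (0.005, 0.05)
    drop_rate_range: tuple[float, float] = (0.0, 0.05)
    cutout_length_range: tuple[float, float] = (0.05, 0.3)   # seconds
    shift_range: tuple[float, float] = (-0.5, 0.5)           # seconds
    resample_factor_range: tuple[float, float] = (0.85, 1.15)
    warp_strength: float = 0.1
    sine_amplitude_range: tuple[float, float] = (0.005, 0.05)
    sine_frequency_range: tuple[float, float] = (0.3, 45.0)
    bandpass_band: tuple[float, float] = (0.2, 45.0)

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        for rng_pair in (self.scaling_range, self.gaussian_sigma_range,
                         self.drop_rate_range, self.cutout_length_range,
                         self.shift_range, self.resample_factor_range,
                         self.sine_amplitude_range, self.sine_frequency_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"degenerate range {rng_pair}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _scaling(x, rate, params, rng):
    return x * params.get("factor", rng.uniform(0.6, 1.4))


def _gaussian_noise(x, rate, params, rng):
    sigma = params.get("sigma", rng.uniform(0.005, 0.05))
    return x + sigma * rng.standard_normal(len(x))


def _drop(x, rate, params, rng):
    p = params.get("rate", rng.uniform(0.0, 0.05))
    out = x.copy()
    out[rng.random(len(x)) < p] = 0.0
    return out


def _cutout(x, rate, params, rng):
    length = int(params.get("length", round(rng.uniform(0.05, 0.3) * rate)))
    length = min(max(length, 0), len(x))
    if length == 0:
        return x.copy()
    start = int(rng.integers(0, len(x) - length + 1))
    out = x.copy()
    out[start:start + length] = 0.0
    return out


def _shift(x, rate, params, rng):
    shift_s = params.get("shift", rng.uniform(-0.5, 0.5))
    k = int(round(shift_s * rate)) if "shift_samples" not in params \
        else int(params["shift_samples"])
    out = np.zeros_like(x)
    if k >= 0:
        out[k:] = x[:len(x) - k] if k < len(x) else 0.0
    else:
        out[:k] = x[-k:]
    return out


def _resample(x, rate, params, rng):
    factor = params.get("factor", rng.uniform(0.85, 1.15))
    return resample(x, rate, rate * factor)


def _random_resample(x, rate, params, rng):
    strength = params.get("strength", 0.1)
    n = len(x)
    n_knots = max(int(params.get("knots", 6)), 3)
    local_rate = 1.0 + strength * rng.uniform(-1.0, 1.0, size=n_knots)
    knot_pos = np.linspace(0, n - 1, n_knots)
    rate_curve = np.interp(np.arange(n), knot_pos, local_rate)
    mapping = np.cumsum(rate_curve)
    mapping = (mapping - mapping[0]) / (mapping[-1] - mapping[0]) * (n - 1)
    return np.interp(mapping, np.arange(n), x)


def _sine(x, rate, params, rng):
    amp = params.get("amplitude", rng.uniform(0.005, 0.05))
    freq = params.get("frequency", rng.uniform(0.3, 45.0))
    phase = params.get("phase", rng.uniform(0.0, 2 * np.pi))
    t = np.arange(len(x)) / rate
    return x + amp * np.sin(2 * np.pi * freq * t + phase)


def _bandpass(x, rate, params, rng):
    band = params.get("band", (0.2, 45.0))
    sos = sps.butter(2, band, btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


# fixed alphabetical registry order for reproducible composition
REGISTRY = {
    "bandpass": _bandpass,
    "cutout": _cutout,
    "drop": _drop,
    "gaussian_noise": _gaussian_noise,
    "random_resample": _random_resample,
    "resample": _resample,
    "scaling": _scaling,
    "shift": _shift,
    "sine": _sine,
}


def apply(samples: np.ndarray, rate: float, name: str,
          params: dict | None = None,
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply one named augmentation; unknown names are rejected."""
    if name not in REGISTRY:
        raise ValueError(f"unknown augmentation {name!r}; "
                         f"expected one of {sorted(REGISTRY)}")
    rng = rng if rng is not None else np.random.default_rng(0)
    x = np.asarray(samples, dtype=np.float64)
    return REGISTRY[name](x, rate, params or {}, rng)


def _policy_params(policy: AugmentationPolicy, name: str, rate: float,
                   rng: np.random.Generator) -> dict:
    if name == "scaling":
        return {"factor": rng.uniform(*policy.scaling_range)}
    if name == "gaussian_noise":
        return {"sigma": rng.uniform(*policy.gaussian_sigma_range)}
    if name == "drop":
        return {"rate": rng.uniform(*policy.drop_rate_range)}
    if name == "cutout":
        return {"length": int(round(
            rng.uniform(*policy.cutout_length_range) * rate))}
    if name == "shift":
        return {"shift": rng.uniform(*policy.shift_range)}
    if name == "resample":
        return {"factor": rng.uniform(*policy.resample_factor_range)}
    if name == "random_resample":
        return {"strength": policy.warp_strength}
    if name == "sine":
        return {"amplitude": rng.uniform(*policy.sine_amplitude_range),
                "frequency": rng.uniform(*policy.sine_frequency_range)}
    if name == "bandpass":
        return {"band": policy.bandpass_band}
    return {}


def compose(samples: np.ndarray, rate: float, policy: AugmentationPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Randomly composed augmentations, deterministic under a fixed rng."""
    x = np.asarray(samples, dtype=np.float64)
    chosen = [name for name in REGISTRY if rng.random() < policy.probability]
    if len(chosen) > policy.max_augmentations:
        idx = rng.choice(len(chosen), size=policy.max_augmentations,
                         replace=False)
        chosen = [chosen[i] for i in sorted(idx)]
    for name in chosen:
        x = REGISTRY[name](x, rate, _policy_params(policy, name, rate, rng), rng)
    return x
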