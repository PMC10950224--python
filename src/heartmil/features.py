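"""Handcrafted explainable features for murmur detection.

The feature set has four blocks, 622 features in total:

* 5 demographic / anthropometric features: age (months), sex, weight,
  height, weight/height;
* 15 duration features: average durations of S1, S2, systole, diastole and
  the full heart cycle, plus all 10 pairwise duration ratios;
* 594 time-frequency features: 18 signal transformations (raw amplitude,
  full-band Hilbert envelope, spectral centroid, spectral bandwidth,
  zero-crossing rate, 13 ms windowed energy, five band-limited Hilbert
  envelopes LF/MF/HF/SF/UF, and seven envelope-ratio signals), each
  summarised by mean/std/max over the whole signal and per heart phase
  (33 statistics and ratios per transformation);
* 8 shape features: normalised cross-correlation of the cycle-averaged
  systolic and diastolic envelopes with the four classic murmur shape
  templates (diamond, plateau, crescendo, decrescendo).

Feature selection trains a gradient-boosted tree classifier on the binary
murmur task and keeps the 20 features with the highest gain importance,
always adding age and weight (relevant for the clinical-outcome head) for a
final set of 22.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import band_envelope, feature_preprocess
from .segmentation import (DIASTOLE, S1, S2, SYSTOLE, Interval,
                           PhaseSegmentation, cycles, segment_phases)

EPS = 1e-8          # denominator floor for all ratio signals and features
SENTINEL = np.nan   # marks missing demographics / absent phases

FREQUENCY_BANDS = {
    "LF": (15.0, 90.0),
    "MF": (55.0, 150.0),
    "HF": (100.0, 250.0),
    "SF": (200.0, 450.0),
    "UF": (400.0, 800.0),
}

# t1..t18; ratio entries name the numerator/denominator envelope bands
TRANSFORMATIONS = (
    ("t1", "absolute amplitude"),
    ("t2", "Hilbert envelope"),
    ("t3", "spectral centroid"),
    ("t4", "spectral bandwidth"),
    ("t5", "zero-crossing rate"),
    ("t6", "windowed energy (13 ms)"),
    ("t7", "LF envelope"),
    ("t8", "MF envelope"),
    ("t9", "HF envelope"),
    ("t10", "SF envelope"),
    ("t11", "UF envelope"),
    ("t12", "HF/LF envelope ratio"),
    ("t13", "HF/MF envelope ratio"),
    ("t14", "MF/LF envelope ratio"),
    ("t15", "SF/MF envelope ratio"),
    ("t16", "SF/LF envelope ratio"),
    ("t17", "UF/LF envelope ratio"),
    ("t18", "(HF+MF)/LF envelope ratio"),
)

SHAPES = ("diamond", "plateau", "crescendo", "decrescendo")

_REGIONS = ("S1", "Sys", "S2", "Dias", "RR")
_STATS = ("a", "s", "m")  # average, standard deviation, maximum
_RATIO_NAMES = (
    # 6 phase-pair mean ratios
    "r_aS1_aS2", "r_aS1_aSys", "r_aS1_aDias",
    "r_aS2_aSys", "r_aS2_aDias", "r_aSys_aDias",
    # 4 phase / full-cycle mean ratios
    "r_aS1_aRR", "r_aS2_aRR", "r_aSys_aRR", "r_aDias_aRR",
    # 5 std/mean ratios, one per region
    "r_sS1_aS1", "r_sS2_aS2", "r_sSys_aSys", "r_sDias_aDias", "r_sRR_aRR",
)
_PHASE_OF_REGION = {"S1": S1, "Sys": SYSTOLE, "S2": S2, "Dias": DIASTOLE}


def shape_template(name: str, n: int) -> np.ndarray:
    """Murmur amplitude templates on n samples, peak-normalised to 1."""
    if n < 1:
        raise ValueError("template length must be positive")
    t = np.linspace(0.0, 1.0, n)
    if name == "crescendo":
        return t
    if name == "decrescendo":
        return 1.0 - t
    if name == "diamond":
        return 1.0 - np.abs(2.0 * t - 1.0)
    if name == "plateau":
        tpl = np.ones(n)
        ramp = t < 0.1
        tpl[ramp] = t[ramp] / 0.1
        ramp = t > 0.9
        tpl[ramp] = (1.0 - t[ramp]) / 0.1
        return tpl
    raise ValueError(f"unknown murmur shape {name!r}")


def demographic_feature_names() -> list[str]:
    return ["age", "sex", "weight", "height", "weight_height"]


# duration block uses S1, S2, Sys, Dias, RR ordering (fixed ratio orientation)
_DUR_REGIONS = ("S1", "S2", "Sys", "Dias", "RR")
_DUR_PAIRS = [(a, b) for i, a in enumerate(_DUR_REGIONS)
              for b in _DUR_REGIONS[i + 1:]]


def duration_feature_names() -> list[str]:
    names = [f"dur_{r}" for r in _DUR_REGIONS]
    names += [f"dur_r_{a}_{b}" for a, b in _DUR_PAIRS]
    return names


def _tf_suffixes() -> list[str]:
    out = list(_STATS)  # whole-signal stats: tX_a, tX_s, tX_m
    for region in _REGIONS:
        out += [f"{stat}{region}" for stat in _STATS]
    out += list(_RATIO_NAMES)
    return out


def tf_feature_names() -> list[str]:
    return [f"{t}_{suffix}" for t, _ in TRANSFORMATIONS for suffix in _tf_suffixes()]


def shape_feature_names() -> list[str]:
    return [f"shape_{s}_{p}" for p in ("sys", "dias") for s in SHAPES]


def feature_names() -> list[str]:
    """Canonical ordering of all 622 feature names."""
    return (demographic_feature_names() + duration_feature_names()
            + tf_feature_names() + shape_feature_names())


def _framewise(samples: np.ndarray, rate: float, frame_s: float = 0.013):
    """Frame the signal (13 ms frames, half-frame hop) for spectral stats."""
    frame = max(8, int(round(frame_s * rate)))
    hop = max(1, frame // 2)
    n = len(samples)
    if n < frame:
        frames = samples[None, :]
        centers = np.array([n / 2.0])
    else:
        starts = np.arange(0, n - frame + 1, hop)
        frames = np.stack([samples[s:s + frame] for s in starts])
        centers = starts + frame / 2.0
    return frames, centers, frame


def _interp_to_length(values: np.ndarray, centers: np.ndarray, n: int) -> np.ndarray:
    if len(values) == 1:
        return np.full(n, values[0])
    return np.interp(np.arange(n), centers, values)


def compute_transformations(samples: np.ndarray, rate: float) -> dict[str, np.ndarray]:
    """The 18 aligned transformation signals t1..t18."""
    x = np.asarray(samples, dtype=np.float64)
    n = len(x)
    if n < rate:
        raise ValueError("need at least one second of signal")
    out: dict[str, np.ndarray] = {}
    out["t1"] = np.abs(x)
    out["t2"] = np.abs(sps.hilbert(x))

    frames, centers, _frame = _framewise(x, rate)
    windowed = frames * np.hanning(frames.shape[1])
    spec = np.abs(np.fft.rfft(windowed, axis=1))
    freqs = np.fft.rfftfreq(windowed.shape[1], d=1.0 / rate)
    mass = spec.sum(axis=1) + EPS
    centroid = (spec * freqs).sum(axis=1) / mass
    bandwidth = np.sqrt((spec * (freqs[None, :] - centroid[:, None]) ** 2
                         ).sum(axis=1) / mass)
    zcr = np.mean(np.abs(np.diff(np.signbit(frames).astype(np.int8), axis=1)),
                  axis=1)
    energy = np.mean(frames ** 2, axis=1)
    out["t3"] = _interp_to_length(centroid, centers, n)
    out["t4"] = _interp_to_length(bandwidth, centers, n)
    out["t5"] = _interp_to_length(zcr, centers, n)
    out["t6"] = _interp_to_length(energy, centers, n)

    envs = {band: band_envelope(x, rate, FREQUENCY_BANDS[band])
            for band in FREQUENCY_BANDS}
    for t, band in zip(("t7", "t8", "t9", "t10", "t11"), FREQUENCY_BANDS):
        out[t] = envs[band]
    ratios = {
        "t12": envs["HF"] / (envs["LF"] + EPS),
        "t13": envs["HF"] / (envs["MF"] + EPS),
        "t14": envs["MF"] / (envs["LF"] + EPS),
        "t15": envs["SF"] / (envs["MF"] + EPS),
        "t16": envs["SF"] / (envs["LF"] + EPS),
        "t17": envs["UF"] / (envs["LF"] + EPS),
        "t18": (envs["HF"] + envs["MF"]) / (envs["LF"] + EPS),
    }
    out.update(ratios)
    return out


def _region_occurrences(segmentation: PhaseSegmentation,
                        region: str) -> list[tuple[int, int]]:
    comp = cycles(segmentation)
    if region == "RR":
        return [(c[0].start, c[3].end) for c in comp]
    label = _PHASE_OF_REGION[region]
    wanted = {id(iv) for c in comp for iv in c}
    return [(iv.start, iv.end) for iv in segmentation.labelled(label)
            if id(iv) in wanted]


def region_stats(tsignal: np.ndarray, segmentation: PhaseSegmentation) -> dict[str, float]:
    """mean/std/max over the whole signal and per phase / full cycle.

    Phase statistics are computed per occurrence and averaged across cycles,
    making them robust to the number of cycles in the recording.
    """
    if not cycles(segmentation):
        raise ValueError("segmentation contains no complete heart cycle")
    x = np.asarray(tsignal, dtype=np.float64)
    out = {"a": float(np.mean(x)), "s": float(np.std(x)), "m": float(np.max(x))}
    for region in _REGIONS:
        occ = [(lo, hi) for lo, hi in _region_occurrences(segmentation, region)
               if hi <= len(x) and hi > lo]
        if not occ:
            for stat in _STATS:
                out[f"{stat}{region}"] = SENTINEL
            continue
        means = [float(np.mean(x[lo:hi])) for lo, hi in occ]
        stds = [float(np.std(x[lo:hi])) for lo, hi in occ]
        maxs = [float(np.max(x[lo:hi])) for lo, hi in occ]
        out[f"a{region}"] = float(np.mean(means))
        out[f"s{region}"] = float(np.mean(stds))
        out[f"m{region}"] = float(np.mean(maxs))
    return out


def stat_ratios(stats: dict[str, float]) -> dict[str, float]:
    """The fixed 15-ratio block derived from one transformation's stats."""
    out = {}
    for name in _RATIO_NAMES:
        _, num, den = name.split("_", 2)
        a, b = stats.get(num, SENTINEL), stats.get(den, SENTINEL)
        if np.isnan(a) or np.isnan(b):
            out[name] = SENTINEL
        else:
            out[name] = float(a / (b + EPS))
    return out


def duration_features(segmentation: PhaseSegmentation,
                      rate: float) -> dict[str, float]:
    """Average phase durations (seconds) and their 10 pairwise ratios."""
    comp = cycles(segmentation)
    if not comp:
        raise ValueError("segmentation contains no complete heart cycle")
    durs = {
        "S1": np.mean([c[0].length for c in comp]) / rate,
        "Sys": np.mean([c[1].length for c in comp]) / rate,
        "S2": np.mean([c[2].length for c in comp]) / rate,
        "Dias": np.mean([c[3].length for c in comp]) / rate,
        "RR": np.mean([c[3].end - c[0].start for c in comp]) / rate,
    }
    out = {f"dur_{r}": float(durs[r]) for r in _DUR_REGIONS}
    for a, b in _DUR_PAIRS:
        out[f"dur_r_{a}_{b}"] = float(durs[a] / (durs[b] + EPS))
    return out


def _phase_mean_envelope(envelope: np.ndarray, occ: list[tuple[int, int]]) -> np.ndarray | None:
    occ = [(lo, hi) for lo, hi in occ if hi <= len(envelope) and hi - lo >= 2]
    if not occ:
        return None
    target = max(4, int(round(np.mean([hi - lo for lo, hi in occ]))))
    grid = np.linspace(0.0, 1.0, target)
    resampled = [np.interp(grid, np.linspace(0.0, 1.0, hi - lo), envelope[lo:hi])
                 for lo, hi in occ]
    return np.mean(resampled, axis=0)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-15:
        return 0.0
    return float(np.dot(a, b) / denom)


def shape_features(envelope: np.ndarray,
                   segmentation: PhaseSegmentation) -> dict[str, float]:
    """Correlation of cycle-averaged phase envelopes with murmur templates."""
    if not cycles(segmentation):
        raise ValueError("segmentation contains no complete heart cycle")
    out = {}
    for region, tag in (("Sys", "sys"), ("Dias", "dias")):
        occ = _region_occurrences(segmentation, region)
        mean_env = _phase_mean_envelope(np.asarray(envelope, dtype=np.float64), occ)
        for shape in SHAPES:
            key = f"shape_{shape}_{tag}"
            if mean_env is None:
                out[key] = SENTINEL
            else:
                out[key] = _ncc(mean_env, shape_template(shape, len(mean_env)))
    return out


def demographic_features(record) -> dict[str, float]:
    """age, sex (0=female, 1=male), weight, height, weight/height."""
    age = SENTINEL if record.age_months is None else float(record.age_months)
    sex = SENTINEL if record.sex is None else float(record.sex == "male")
    weight = SENTINEL if record.weight_kg is None else float(record.weight_kg)
    height = SENTINEL if record.height_cm is None else float(record.height_cm)
    wh = SENTINEL if (np.isnan(weight) or np.isnan(height)) else weight / height
    return {"age": age, "sex": sex, "weight": weight, "height": height,
            "weight_height": wh}


def extract_features(samples: np.ndarray, rate: float,
                     segmentation: PhaseSegmentation,
                     demographics) -> pd.Series:
    """The full, ordered 622-entry feature vector for one recording.

    The samples are expected to have gone through the feature-chain
    preprocessing (despike, edge clip, envelope clip); the segmentation must
    be aligned to them.
    """
    values: dict[str, float] = {}
    values.update(demographic_features(demographics))
    values.update(duration_features(segmentation, rate))
    tsignals = compute_transformations(samples, rate)
    for t, _desc in TRANSFORMATIONS:
        stats = region_stats(tsignals[t], segmentation)
        for stat in _STATS:
            values[f"{t}_{stat}"] = stats[stat]
        for region in _REGIONS:
            for stat in _STATS:
                values[f"{t}_{stat}{region}"] = stats[f"{stat}{region}"]
        for name, val in stat_ratios(stats).items():
            values[f"{t}_{name}"] = val
    values.update(shape_features(tsignals["t2"], segmentation))
    names = feature_names()
    if set(values) != set(names) or len(names) != 622:
        raise RuntimeError("feature vector does not have the canonical 622 entries")
    return pd.Series(values).reindex(names)


def crop_segmentation(segmentation: PhaseSegmentation, start: int,
                      end: int) -> PhaseSegmentation:
    """Restrict a segmentation to [start, end) and shift to 0-based indices."""
    kept = []
    for iv in segmentation:
        lo, hi = max(iv.start, start), min(iv.end, end)
        if hi - lo == iv.length:  # only keep fully contained intervals
            kept.append(Interval(lo - start, hi - start, iv.label))
    return PhaseSegmentation(kept)


def recording_features(recording, use_reference_segmentation: bool = True) -> pd.Series:
    """Feature-chain preprocessing + extraction for one recording object."""
    samples, offset = feature_preprocess(recording.samples,
                                         recording.sampling_rate)
    if use_reference_segmentation and recording.segmentation is not None:
        seg = crop_segmentation(recording.segmentation, offset,
                                offset + len(samples))
    else:
        seg = segment_phases(samples, recording.sampling_rate)
    return extract_features(samples, recording.sampling_rate, seg,
                            recording.demographics)


@dataclass
class SelectionResult:
    ranking: list[tuple[str, float]]       # all features, importance-sorted
    selected: list[str]                    # top-k plus age and weight

    @property
    def importances(self) -> dict[str, float]:
        return dict(self.ranking)


def rank_and_select(feature_table: pd.DataFrame, binary_murmur_labels,
                    k: int = 20, always_keep: tuple[str, ...] = ("age", "weight"),
                    seed: int = 0) -> SelectionResult:
    """Gain-importance ranking via gradient-boosted trees, then top-k + extras."""
    import xgboost as xgb

    y = np.asarray(binary_murmur_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to rank features")
    # strong column subsampling spreads gain across correlated features
    # (the 622 features are heavily redundant; without it a single good
    # feature can absorb every split and the ranking degenerates)
    model = xgb.XGBClassifier(
        n_estimators=500, max_depth=3, learning_rate=0.05,
        colsample_bytree=0.05, subsample=0.8,
        tree_method="hist", n_jobs=1, random_state=seed,
        eval_metric="logloss", base_score=0.5)
    model.fit(feature_table, y)
    gain = model.get_booster().get_score(importance_type="gain")
    importances = {name: float(gain.get(name, 0.0))
                   for name in feature_table.columns}
    ranking = sorted(importances.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = [name for name, _ in ranking[:k]]
    for extra in always_keep:
        if extra not in selected and extra in feature_table.columns:
            selected.append(extra)
    return SelectionResult(ranking=ranking, selected=selected)


class HandcraftedFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer mapping recordings to the 622-feature table."""

    def __init__(self, use_reference_segmentation: bool = True):
        self.use_reference_segmentation = use_reference_segmentation

    def fit(self, X, y=None):
        self.feature_names_ = feature_names()
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [recording_features(rec, self.use_reference_segmentation)
                for rec in X]
        return pd.DataFrame(rows).reset_index(drop=True)


class ImportanceFeatureSelector(BaseEstimator, TransformerMixin):
    """Select top-k gain-importance features (plus age/weight) for murmur."""

    def __init__(self, k: int = 20, always_keep: tuple[str, ...] = ("age", "weight"),
                 seed: int = 0):
        self.k = k
        self.always_keep = always_keep
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        result = rank_and_select(X, y, k=self.k, always_keep=self.always_keep,
                                 seed=self.seed)
        self.ranking_ = result.ranking
        self.selected_features_ = result.selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]
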