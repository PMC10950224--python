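"""Patient-level multitask classifier (stage 2).

Fuses, per patient: the 22 selected handcrafted features (averaged over the
patient's recordings), the PANN encoded features (20) and class
probabilities (3) for each of the four standard auscultation locations
(with explicit missing-location mask bits), and the demographic features
age and weight.  A five-layer feed-forward network (hidden sizes 123, 492,
246, 20; batch norm + leaky ReLU + dropout after each hidden layer) ends in
two softmax heads: 3 murmur classes (Absent, Unknown, Present) and 2
clinical outcomes (Normal, Abnormal).

The loss is the sum of two weighted cross-entropies; per-class weights are
the inverse relative class frequencies multiplied by the clinical factors
[1, 3, 5] (Absent, Unknown, Present) and [1, 5] (Normal, Abnormal), echoing
the weighted-accuracy metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _nn

MURMUR_ORDER = ("Absent", "Unknown", "Present")
OUTCOME_ORDER = ("Normal", "Abnormal")
MURMUR_FACTORS = (1.0, 3.0, 5.0)
OUTCOME_FACTORS = (1.0, 5.0)
STANDARD_LOCATIONS = ("AV", "PV", "TV", "MV")


@dataclass(frozen=True)
class Stage2Config:
    hidden: tuple[int, ...] = (123, 492, 246, 20)
    dropout: float = 0.1
    leaky_slope: float = 0.01


@dataclass
class PatientFeatureSet:
    vector: np.ndarray
    names: list[str]
    location_mask: np.ndarray     # 1 where the location was recorded

    def __post_init__(self):
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("patient feature vector contains non-finite values")


@dataclass
class PatientPrediction:
    murmur_probs: np.ndarray      # (Absent, Unknown, Present)
    outcome_probs: np.ndarray     # (Normal, Abnormal)

    @property
    def murmur_label(self) -> str:
        return MURMUR_ORDER[int(np.argmax(self.murmur_probs))]

    @property
    def outcome_label(self) -> str:
        return OUTCOME_ORDER[int(np.argmax(self.outcome_probs))]


def assemble_patient_features(patient, recording_predictions: dict,
                              selected_features: pd.Series) -> PatientFeatureSet:
    """Fuse handcrafted, PANN and demographic features for one patient.

    ``recording_predictions`` maps location -> RecordingPrediction; missing
    locations are zero-filled and flagged in the mask.  NaN sentinels in the
    handcrafted block (missing demographics) are imputed to zero.
    """
    if not recording_predictions and selected_features.empty:
        raise ValueError("patient has no recordings")
    names: list[str] = list(selected_features.index)
    values: list[float] = list(np.nan_to_num(selected_features.to_numpy(
        dtype=np.float64), nan=0.0))
    n_feats = None
    for pred in recording_predictions.values():
        n_feats = len(pred.features)
        break
    n_feats = 20 if n_feats is None else n_feats
    mask = np.zeros(len(STANDARD_LOCATIONS))
    for i, loc in enumerate(STANDARD_LOCATIONS):
        pred = recording_predictions.get(loc)
        if pred is not None:
            mask[i] = 1.0
            values += list(pred.features) + list(pred.probabilities)
        else:
            values += [0.0] * (n_feats + 3)
        names += [f"pann_{loc}_f{j}" for j in range(n_feats)]
        names += [f"pann_{loc}_p{c}" for c in ("P", "U", "A")]
    demo = getattr(patient, "demographics", None)
    age = 0.0 if demo is None or demo.age_months is None else float(demo.age_months)
    weight = 0.0 if demo is None or demo.weight_kg is None else float(demo.weight_kg)
    values += [age, weight]
    names += ["age_months", "weight_kg"]
    values += list(mask)
    names += [f"has_{loc}" for loc in STANDARD_LOCATIONS]
    return PatientFeatureSet(np.asarray(values, dtype=np.float64), names, mask)


def class_weight_vector(labels, order: tuple[str, ...],
                        factors: tuple[float, ...]) -> np.ndarray:
    """Inverse relative class frequency times the clinical class factors."""
    counts = np.array([max(sum(1 for lab in labels if lab == c), 1)
                       for c in order], dtype=np.float64)
    inv = len(labels) / counts
    inv /= inv.mean()
    return inv * np.asarray(factors)


def stage2_loss(prediction, labels, weights) -> float:
    """Sum of the two weighted cross-entropy terms for one patient.

    ``prediction`` = (murmur probs, outcome probs); ``labels`` = (murmur
    label or index, outcome label or index); ``weights`` = (3-vector,
    2-vector) of per-class weights.
    """
    (pm, po), (ym, yo), (wm, wo) = prediction, labels, weights
    im = MURMUR_ORDER.index(ym) if isinstance(ym, str) else int(ym)
    io = OUTCOME_ORDER.index(yo) if isinstance(yo, str) else int(yo)
    eps = 1e-12
    term_m = -float(wm[im]) * float(np.log(max(float(pm[im]), eps)))
    term_o = -float(wo[io]) * float(np.log(max(float(po[io]), eps)))
    return term_m + term_o


class _Stage2Net:
    def __init__(self, n_inputs: int, config: Stage2Config, seed: int):
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        self.layers = []
        prev = n_inputs
        for h in config.hidden:
            self.layers += [
                _nn.Linear(prev, h, rng),
                _nn.BatchNorm1d(h),
                _nn.LeakyReLU(config.leaky_slope),
                _nn.Dropout(config.dropout, drop_rng),
            ]
            prev = h
        self.head = _nn.Linear(prev, len(MURMUR_ORDER) + len(OUTCOME_ORDER), rng)

    def _all(self):
        return self.layers + [self.head]

    def parameters(self):
        return [p for l in self._all() for p in l.parameters()]

    def forward(self, x: np.ndarray, training: bool):
        h = x.astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h, training)
        logits = self.head.forward(h, training)
        return logits[:, :3], logits[:, 3:]

    def backward(self, gm: np.ndarray, go: np.ndarray):
        g = self.head.backward(np.concatenate([gm, go], axis=1).astype(np.float32))
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def state_dict(self):
        return _nn.state_dict(self._all())

    def load_state(self, state):
        _nn.load_state(self._all(), state)


class PatientMultitaskClassifier(BaseEstimator):
    """Joint murmur (3-class) and clinical outcome (2-class) prediction."""

    def __init__(self, config: Stage2Config | None = None, epochs: int = 300,
                 batch_size: int = 32, lr: float = 1e-3, random_state: int = 0):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y_murmur, y_outcome):
        X = np.asarray(X, dtype=np.float64)
        ym = np.array([MURMUR_ORDER.index(lab) if isinstance(lab, str) else int(lab)
                       for lab in y_murmur])
        yo = np.array([OUTCOME_ORDER.index(lab) if isinstance(lab, str) else int(lab)
                       for lab in y_outcome])
        if len(np.unique(ym)) < 2 or len(np.unique(yo)) < 2:
            raise ValueError("both tasks need at least two classes in training")
        cfg = self.config or Stage2Config()
        rng = np.random.default_rng(self.random_state)
        net = _Stage2Net(X.shape[1], cfg, seed=int(rng.integers(2 ** 31)))
        self.murmur_weights_ = class_weight_vector(
            [MURMUR_ORDER[i] for i in ym], MURMUR_ORDER, MURMUR_FACTORS)
        self.outcome_weights_ = class_weight_vector(
            [OUTCOME_ORDER[i] for i in yo], OUTCOME_ORDER, OUTCOME_FACTORS)
        # standardise inputs; scale is stored for inference
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        Xs = (X - self.mean_) / self.scale_

        opt = _nn.Adam(net.parameters(), lr=self.lr)
        history = []
        for _epoch in range(self.epochs):
            order = rng.permutation(len(ym))
            ep_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                if len(batch) < 2:
                    continue  # batch norm needs more than one row
                opt.zero_grad()
                lm, lo = net.forward(Xs[batch], training=True)
                pm = _nn.softmax(lm.astype(np.float64), axis=1)
                po = _nn.softmax(lo.astype(np.float64), axis=1)
                bm, bo = ym[batch], yo[batch]
                wm = self.murmur_weights_[bm]
                wo = self.outcome_weights_[bo]
                n = len(batch)
                loss = float(
                    np.mean(-wm * np.log(np.clip(pm[np.arange(n), bm], 1e-12, None)))
                    + np.mean(-wo * np.log(np.clip(po[np.arange(n), bo], 1e-12, None))))
                gm = pm.copy()
                gm[np.arange(n), bm] -= 1.0
                gm *= (wm / n)[:, None]
                go = po.copy()
                go[np.arange(n), bo] -= 1.0
                go *= (wo / n)[:, None]
                net.backward(gm, go)
                opt.step()
                ep_loss += loss * n
            history.append(ep_loss / len(ym))
        self.net_ = net
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.float64)
        Xs = (X - self.mean_) / self.scale_
        lm, lo = self.net_.forward(Xs, training=False)
        return (_nn.softmax(lm.astype(np.float64), axis=1),
                _nn.softmax(lo.astype(np.float64), axis=1))

    def predict(self, X) -> tuple[list[str], list[str]]:
        pm, po = self.predict_proba(X)
        return ([MURMUR_ORDER[i] for i in pm.argmax(axis=1)],
                [OUTCOME_ORDER[i] for i in po.argmax(axis=1)])

    def predict_patient(self, features: PatientFeatureSet) -> PatientPrediction:
        pm, po = self.predict_proba(features.vector[None, :])
        return PatientPrediction(pm[0], po[0])


def train_stage2(feature_table, y_murmur, y_outcome,
                 config: Stage2Config | None = None, seed: int = 0,
                 **kwargs) -> PatientMultitaskClassifier:
    clf = PatientMultitaskClassifier(config=config, random_state=seed, **kwargs)
    clf.fit(feature_table, y_murmur, y_outcome)
    return clf


def predict_patient(model: PatientMultitaskClassifier,
                    features: PatientFeatureSet) -> PatientPrediction:
    return model.predict_patient(features)
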