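"""Pooling-based artificial neural network (stage 1).

A convolutional encoder of six base blocks (two kernel-5 'same'
convolutions with batch normalisation and dropout, then stride-2 max
pooling) maps a variable-length recording to a 64-channel feature map.
Adaptive pooling summarises each channel with a fixed-size vector: 15
max-pooled, 10 average-pooled and 5 min-pooled segments (30 values per
channel), approximating softmax pooling while staying robust to noisy
stretches.  The pooled 30 x 64 block, concatenated with a 5-dim one-hot
auscultation location, feeds a fully connected head (100 hidden, 20 output
neurons) and a linear softmax decision layer over the three recording-level
murmur classes (Present / Unknown / Absent).

After training, the network is used purely as a feature generator: the
20-dim encoded output and the 3 class probabilities per recording feed the
patient-level second stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn
from .augment import AugmentationPolicy, compose

LOCATIONS = ("AV", "PV", "TV", "MV", "other")
PANN_CLASSES = ("Present", "Unknown", "Absent")


@dataclass(frozen=True)
class PANNConfig:
    channels: tuple[int, ...] = (16, 24, 32, 40, 52, 64)
    kernel_size: int = 5
    dropout: float = 0.1
    pool_sizes: tuple[int, int, int] = (15, 10, 5)   # max / avg / min
    hidden: int = 100
    out_features: int = 20
    n_classes: int = 3

    def __post_init__(self):
        if sum(self.pool_sizes) != 30:
            raise ValueError("adaptive pooling sizes must sum to 30")
        if len(self.channels) != 6:
            raise ValueError("the encoder has 6 base blocks")


@dataclass
class RecordingPrediction:
    probabilities: np.ndarray       # (Present, Unknown, Absent)
    features: np.ndarray            # 20-dim encoded output
    pooled: np.ndarray              # (channels, 30) adaptive-pooled block


def location_onehot(location: str) -> np.ndarray:
    if location not in LOCATIONS:
        raise ValueError(f"unknown location {location!r}")
    v = np.zeros(len(LOCATIONS), dtype=np.float32)
    v[LOCATIONS.index(location)] = 1.0
    return v


def class_weights(labels, classes: tuple[str, ...] = PANN_CLASSES) -> np.ndarray:
    """Inverse relative class occurrence, normalised to mean 1."""
    counts = np.array([max(sum(1 for lab in labels if lab == c), 1)
                       for c in classes], dtype=np.float64)
    w = (len(labels) / counts)
    return w / w.mean()


class PANN:
    """The encoder + adaptive pooling + fully connected head."""

    def __init__(self, config: PANNConfig | None = None, seed: int = 0):
        cfg = config or PANNConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        self.blocks = []
        prev = 1
        for ch in cfg.channels:
            self.blocks.append((
                _nn.Conv1d(prev, ch, cfg.kernel_size, rng),
                _nn.BatchNorm1d(ch),
                _nn.ReLU(),
                _nn.Conv1d(ch, ch, cfg.kernel_size, rng),
                _nn.ReLU(),
                _nn.Dropout(cfg.dropout, self.drop_rng),
                _nn.MaxPool1d(),
            ))
            prev = ch
        self.pool_max = _nn.AdaptiveMaxPool1d(cfg.pool_sizes[0])
        self.pool_avg = _nn.AdaptiveAvgPool1d(cfg.pool_sizes[1])
        self.pool_min = _nn.AdaptiveMinPool1d(cfg.pool_sizes[2])
        n_flat = prev * sum(cfg.pool_sizes)
        self.fc1 = _nn.Linear(n_flat + len(LOCATIONS), cfg.hidden, rng)
        self.act1 = _nn.ReLU()
        self.fc2 = _nn.Linear(cfg.hidden, cfg.out_features, rng)
        self.act2 = _nn.ReLU()
        self.decision = _nn.Linear(cfg.out_features, cfg.n_classes, rng)

    def _layers(self):
        layers = [l for block in self.blocks for l in block]
        layers += [self.fc1, self.act1, self.fc2, self.act2, self.decision]
        return layers

    def parameters(self):
        return [p for l in self._layers() for p in l.parameters()]

    def encode(self, x: np.ndarray, training: bool) -> np.ndarray:
        min_len = 2 ** len(self.blocks)
        if x.shape[2] < min_len:
            raise ValueError(f"input shorter than {min_len} samples")
        if x.shape[2] % min_len:
            raise ValueError(f"input length must be divisible by {min_len}")
        h = x
        for block in self.blocks:
            for layer in block:
                h = layer.forward(h, training)
        return h

    def forward(self, x: np.ndarray, loc: np.ndarray, training: bool = True):
        """x: (B, 1, T), loc: (B, 5) -> (logits, features, pooled)."""
        h = self.encode(x, training)
        pooled = np.concatenate([self.pool_max.forward(h, training),
                                 self.pool_avg.forward(h, training),
                                 self.pool_min.forward(h, training)], axis=2)
        flat = pooled.reshape(pooled.shape[0], -1)
        self._pool_shape = pooled.shape
        z = np.concatenate([flat, loc.astype(flat.dtype)], axis=1)
        hdn = self.act1.forward(self.fc1.forward(z, training), training)
        feats = self.act2.forward(self.fc2.forward(hdn, training), training)
        logits = self.decision.forward(feats, training)
        return logits, feats, pooled

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.decision.backward(grad_logits)
        g = self.fc2.backward(self.act2.backward(g))
        g = self.fc1.backward(self.act1.backward(g))
        g = g[:, : -len(LOCATIONS)]            # drop the one-hot gradient
        g = g.reshape(self._pool_shape)
        m = self.config.pool_sizes
        g_max, g_avg, g_min = np.split(g, [m[0], m[0] + m[1]], axis=2)
        dh = (self.pool_max.backward(np.ascontiguousarray(g_max))
              + self.pool_avg.backward(np.ascontiguousarray(g_avg))
              + self.pool_min.backward(np.ascontiguousarray(g_min)))
        for block in reversed(self.blocks):
            for layer in reversed(block):
                dh = layer.backward(dh)

    def state_dict(self):
        return _nn.state_dict(self._layers())

    def load_state(self, state):
        _nn.load_state(self._layers(), state)


def build_pann(config: PANNConfig | None = None, seed: int = 0) -> PANN:
    return PANN(config, seed)


def _prepare(samples: np.ndarray, length: int) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float32)
    if len(x) >= length:
        return x[:length]
    return np.pad(x, (0, length - len(x)))


def pann_features(model: PANN, samples: np.ndarray,
                  location: str) -> RecordingPrediction:
    """Inference-mode prediction + features for one recording."""
    block = 2 ** len(model.blocks)
    x = np.asarray(samples, dtype=np.float32)
    pad = (-len(x)) % block
    xb = np.pad(x, (0, pad))[None, None, :]
    logits, feats, pooled = model.forward(xb, location_onehot(location)[None, :],
                                          training=False)
    return RecordingPrediction(probabilities=_nn.softmax(logits[0]),
                               features=feats[0].astype(np.float64),
                               pooled=pooled[0].astype(np.float64))


class PANNFeatureGenerator(BaseEstimator, TransformerMixin):
    """Trains the PANN on recording-level murmur labels, then generates features."""

    def __init__(self, config: PANNConfig | None = None, epochs: int = 40,
                 batch_size: int = 32, lr: float = 1e-3, lr_decay: float = 0.3,
                 lr_step_epochs: int = 30, fixed_length: int = 2 ** 13,
                 val_fraction: float = 0.2,
                 augment_policy: AugmentationPolicy | None = AugmentationPolicy(),
                 random_state: int = 0):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_step_epochs = lr_step_epochs
        self.fixed_length = fixed_length
        self.val_fraction = val_fraction
        self.augment_policy = augment_policy
        self.random_state = random_state

    def _weighted_ce(self, logits, y_idx, w):
        probs = _nn.softmax(logits.astype(np.float64), axis=1)
        wi = w[y_idx]
        ll = -np.log(np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-12, None))
        loss = float(np.sum(wi * ll) / np.sum(wi))
        grad = probs
        grad[np.arange(len(y_idx)), y_idx] -= 1.0
        grad *= (wi / np.sum(wi))[:, None]
        return loss, grad.astype(np.float32)

    def fit(self, recordings, y=None):
        labels = list(y) if y is not None else [r.murmur_label for r in recordings]
        missing = [c for c in PANN_CLASSES if c not in labels]
        if missing:
            raise ValueError(f"training data lacks classes {missing}")
        y_idx = np.array([PANN_CLASSES.index(lab) for lab in labels])
        rng = np.random.default_rng(self.random_state)
        model = PANN(self.config, seed=int(rng.integers(2 ** 31)))
        self.class_weights_ = class_weights(labels)
        rate = getattr(recordings[0], "sampling_rate", 2000.0)
        raw = [np.asarray(self._samples(r), dtype=np.float64) for r in recordings]
        X = np.stack([_prepare(x, self.fixed_length) for x in raw])
        locs = np.stack([location_onehot(getattr(r, "location", "other"))
                         for r in recordings])

        idx = np.arange(len(y_idx))
        val_mask = np.zeros(len(y_idx), dtype=bool)
        for c in range(len(PANN_CLASSES)):
            cls_idx = idx[y_idx == c]
            cls_idx = cls_idx[rng.permutation(len(cls_idx))]
            val_mask[cls_idx[: max(1, int(round(self.val_fraction * len(cls_idx))))]] = True
        tr_idx, va_idx = idx[~val_mask], idx[val_mask]

        opt = _nn.Adam(model.parameters(), lr=self.lr)
        best_state, best_score = model.state_dict(), -np.inf
        history = {"train_acc": [], "val_acc": [], "train_loss": []}
        for epoch in range(self.epochs):
            opt.lr = self.lr * (self.lr_decay ** (epoch // self.lr_step_epochs))
            order = tr_idx[rng.permutation(len(tr_idx))]
            losses, correct = [], 0
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                if self.augment_policy is not None:
                    xb = np.stack([
                        _prepare(compose(raw[i], rate, self.augment_policy, rng),
                                 self.fixed_length) for i in batch])
                else:
                    xb = X[batch]
                opt.zero_grad()
                logits, _, _ = model.forward(xb[:, None, :], locs[batch],
                                             training=True)
                loss, grad = self._weighted_ce(logits, y_idx[batch],
                                               self.class_weights_)
                model.backward(grad)
                opt.step()
                losses.append(loss)
                correct += int(np.sum(logits.argmax(axis=1) == y_idx[batch]))
            train_acc = correct / len(order)
            val_logits, _, _ = model.forward(X[va_idx][:, None, :], locs[va_idx],
                                             training=False)
            val_acc = float(np.mean(val_logits.argmax(axis=1) == y_idx[va_idx]))
            history["train_acc"].append(train_acc)
            history["val_acc"].append(val_acc)
            history["train_loss"].append(float(np.mean(losses)))
            score = 0.5 * (train_acc + val_acc)
            if score > best_score:
                best_score, best_state = score, model.state_dict()
        if self.epochs > 0:
            model.load_state(best_state)
        self.model_ = model
        self.history_ = history
        return self

    @staticmethod
    def _samples(rec):
        return rec.samples if hasattr(rec, "samples") else np.asarray(rec)

    def predict_recording(self, recording, location: str | None = None) -> RecordingPrediction:
        loc = location or getattr(recording, "location", "other")
        return pann_features(self.model_, self._samples(recording), loc)

    def transform(self, recordings) -> list[RecordingPrediction]:
        return [self.predict_recording(r) for r in recordings]

    def score(self, recordings, y=None) -> float:
        labels = list(y) if y is not None else [r.murmur_label for r in recordings]
        preds = [PANN_CLASSES[int(np.argmax(self.predict_recording(r).probabilities))]
                 for r in recordings]
        return float(np.mean([p == t for p, t in zip(preds, labels)]))


def train_pann(recordings, y=None, seed: int = 0, **kwargs) -> PANNFeatureGenerator:
    gen = PANNFeatureGenerator(random_state=seed, **kwargs)
    gen.fit(recordings, y)
    return gen
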