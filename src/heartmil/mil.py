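"""Multiple-instance murmur localisation with a 1D U-Net.

A phonocardiogram is treated as a *bag* of instances (one instance per
output sample); the recording-level murmur tag is the only label.  A fully
convolutional U-Net (5 downsampling steps, kernel size 5, ReLU) produces a
per-sample murmur probability ("murmurness"), and softmax pooling condenses
the instance probabilities into a bag probability

    P = sum_x p(x) * exp(p(x)) / sum_z exp(p(z)),

which interpolates between mean pooling and max pooling: every instance
contributes, but the most confident instances dominate.  Training minimises
binary cross-entropy between the pooled bag probability and the weak label.

Postprocessing thresholds the murmurness trace at 0.6, finds prominent
peaks and merges peaks closer than 60 ms into murmur segments.  The
explainability evaluation scores, per recording, the fraction of segments
overlapping the annotated murmur phase (phase precision); recordings with
no segments are flagged ``NO_ACTIVATION``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from . import _nn
from .segmentation import DIASTOLE, SYSTOLE, PhaseSegmentation

NO_ACTIVATION = "no_activation"

_PHASES_FOR = {"systolic": (SYSTOLE,), "diastolic": (DIASTOLE,),
               "both": (SYSTOLE, DIASTOLE)}


@dataclass
class MILBag:
    """One recording as a bag of per-sample instances with a weak label."""

    instances: np.ndarray
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("bag label must be 0 or 1")


@dataclass
class MurmurSegment:
    start: int
    end: int
    peak: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment must be non-empty")


@dataclass(frozen=True)
class MILTrainConfig:
    batch_size: int = 128
    lr: float = 1e-3
    lr_decay: float = 0.5
    lr_step_epochs: int = 10
    epochs: int = 30
    fixed_length: int = 2 ** 14
    val_fraction: float = 0.2
    patience: int = 10

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be positive and batch_size >= 1")


def softmax_pool(instance_probs: np.ndarray) -> float:
    """Softmax-weighted pooling of instance probabilities into a bag probability."""
    p = np.asarray(instance_probs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("cannot pool an empty set of instances")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("instance probabilities must lie in [0, 1]")
    w = np.exp(p - p.max())
    w /= w.sum()
    return float(np.sum(p * w))


class MILUNet:
    """Fully convolutional 1D U-Net emitting per-sample murmur logits."""

    def __init__(self, base_channels: int = 4, depth: int = 5,
                 kernel_size: int = 5, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        ch = [base_channels * (i + 1) for i in range(depth + 1)]
        self.channels = ch
        self.enc = []
        prev = 1
        for i in range(depth):
            self.enc.append((_nn.Conv1d(prev, ch[i], kernel_size, rng),
                             _nn.ReLU(), _nn.AvgPool1d()))
            prev = ch[i]
        self.bottleneck = (_nn.Conv1d(ch[depth - 1], ch[depth], kernel_size, rng),
                           _nn.ReLU())
        self.dec = []
        prev = ch[depth]
        for i in reversed(range(depth)):
            self.dec.append((_nn.Upsample1d(),
                             _nn.Conv1d(prev + ch[i], ch[i], kernel_size, rng),
                             _nn.ReLU()))
            prev = ch[i]
        self.out_conv = _nn.Conv1d(ch[0], 1, kernel_size, rng)

    def parameters(self) -> list[_nn.Param]:
        params = []
        for conv, _relu, _pool in self.enc:
            params += conv.parameters()
        params += self.bottleneck[0].parameters()
        for _up, conv, _relu in self.dec:
            params += conv.parameters()
        params += self.out_conv.parameters()
        return params

    def _all_layers(self):
        layers = []
        for block in self.enc:
            layers += list(block)
        layers += list(self.bottleneck)
        for block in self.dec:
            layers += list(block)
        layers.append(self.out_conv)
        return layers

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """x: (batch, 1, T) with T divisible by 2**depth -> logits (batch, T)."""
        if x.ndim != 3:
            raise ValueError("expected (batch, 1, time) input")
        if x.shape[2] % (2 ** self.depth) != 0:
            raise ValueError(f"input length must be divisible by {2 ** self.depth}")
        skips = []
        h = x
        for conv, relu, pool in self.enc:
            h = relu.forward(conv.forward(h, training), training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck[1].forward(
            self.bottleneck[0].forward(h, training), training)
        self._skip_channels = [s.shape[1] for s in skips]
        for (up, conv, relu), skip in zip(self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([h, skip], axis=1)
            h = relu.forward(conv.forward(h, training), training)
        logits = self.out_conv.forward(h, training)
        return logits[:, 0, :]

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.out_conv.backward(grad_logits[:, None, :])
        skip_grads = [None] * self.depth
        for j, (up, conv, relu) in enumerate(reversed(self.dec)):
            # reversed(dec) runs from the last decoder block back to the first
            level = j  # decoder block j consumed skip[level]
            g = conv.backward(relu.backward(g))
            n_up = g.shape[1] - self._skip_channels[level]
            g_up, g_skip = g[:, :n_up, :], g[:, n_up:, :]
            skip_grads[level] = g_skip
            g = up.backward(g_up)
        g = self.bottleneck[0].backward(self.bottleneck[1].backward(g))
        for i in reversed(range(self.depth)):
            conv, relu, pool = self.enc[i]
            g = pool.backward(g)
            g = g + skip_grads[i]
            g = conv.backward(relu.backward(g))

    def state_dict(self):
        return _nn.state_dict(self._all_layers())

    def load_state(self, state):
        _nn.load_state(self._all_layers(), state)


def build_mil_unet(base_channels: int = 4, depth: int = 5,
                   kernel_size: int = 5, seed: int = 0) -> MILUNet:
    return MILUNet(base_channels, depth, kernel_size, seed)


def _pooled_and_grad(p: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masked softmax pooling per row plus dP/dp (rows: bags)."""
    w = np.exp(p - np.max(np.where(valid, p, -np.inf), axis=1, keepdims=True))
    w = np.where(valid, w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    pooled = np.sum(p * w, axis=1)
    grad = w * (1.0 + p - pooled[:, None])
    return pooled, np.where(valid, grad, 0.0)


def _prepare_bag(samples: np.ndarray, length: int) -> tuple[np.ndarray, int]:
    x = np.asarray(samples, dtype=np.float32)
    if len(x) >= length:
        return x[:length], length
    out = np.zeros(length, dtype=np.float32)
    out[:len(x)] = x
    return out, len(x)


def murmurness(model: MILUNet, samples: np.ndarray) -> np.ndarray:
    """Per-sample murmur probability trace, same length as the input."""
    x = np.asarray(samples, dtype=np.float32)
    block = 2 ** model.depth
    pad = (-len(x)) % block
    xp = np.pad(x, (0, pad))
    logits = model.forward(xp[None, None, :], training=False)[0]
    return _nn.sigmoid(logits[: len(x)]).astype(np.float64)


def bag_probability(model: MILUNet, samples: np.ndarray) -> float:
    return softmax_pool(murmurness(model, samples))


def postprocess(trace: np.ndarray, rate: float, threshold: float = 0.6,
                merge_ms: float = 60.0, prominence: float = 0.1) -> list[MurmurSegment]:
    """Threshold + prominent-peak detection + 60 ms merge of a murmurness trace."""
    t = np.asarray(trace, dtype=np.float64)
    peaks, _props = sps.find_peaks(t, height=threshold, prominence=prominence)
    if len(peaks) == 0:
        return []
    mask = t >= threshold
    merge_gap = merge_ms / 1000.0 * rate
    groups: list[list[int]] = [[int(peaks[0])]]
    for pk in peaks[1:]:
        if pk - groups[-1][-1] <= merge_gap:
            groups[-1].append(int(pk))
        else:
            groups.append([int(pk)])
    segments = []
    for group in groups:
        lo = group[0]
        while lo > 0 and mask[lo - 1]:
            lo -= 1
        hi = group[-1]
        while hi < len(t) - 1 and mask[hi + 1]:
            hi += 1
        segments.append(MurmurSegment(lo, hi + 1, float(np.max(t[lo:hi + 1]))))
    return segments


def phase_precision(segments: list[MurmurSegment],
                    segmentation: PhaseSegmentation,
                    murmur_phase: str = "systolic"):
    """Fraction of murmur segments overlapping the annotated murmur phase.

    Returns ``NO_ACTIVATION`` when there are no segments at all.
    """
    if murmur_phase not in _PHASES_FOR:
        raise ValueError(f"murmur_phase must be one of {sorted(_PHASES_FOR)}")
    if not segments:
        return NO_ACTIVATION
    labels = _PHASES_FOR[murmur_phase]
    intervals = [iv for lab in labels for iv in segmentation.labelled(lab)]
    hits = sum(1 for seg in segments
               if any(iv.overlaps(seg.start, seg.end) for iv in intervals))
    return hits / len(segments)


def pseudo_precision(segments: list[MurmurSegment],
                     segmentation: PhaseSegmentation):
    """Phase precision of murmur-absent recordings, assuming systolic murmur."""
    return phase_precision(segments, segmentation, "systolic")


class MILUNetDetector(BaseEstimator):
    """Weakly supervised murmur detector and localiser.

    Fits the MIL U-Net on recording-level binary murmur labels and exposes
    per-sample murmurness, bag probabilities and postprocessed murmur
    segments.  Recordings labelled "Unknown" are excluded from training.
    """

    def __init__(self, base_channels: int = 4, depth: int = 5,
                 kernel_size: int = 5, epochs: int = 30, batch_size: int = 128,
                 lr: float = 1e-3, lr_decay: float = 0.5, lr_step_epochs: int = 10,
                 fixed_length: int = 2 ** 14, val_fraction: float = 0.2,
                 patience: int = 10, threshold: float = 0.6,
                 merge_ms: float = 60.0, random_state: int = 0):
        self.base_channels = base_channels
        self.depth = depth
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_step_epochs = lr_step_epochs
        self.fixed_length = fixed_length
        self.val_fraction = val_fraction
        self.patience = patience
        self.threshold = threshold
        self.merge_ms = merge_ms
        self.random_state = random_state

    @staticmethod
    def _samples_of(rec) -> np.ndarray:
        return rec.samples if hasattr(rec, "samples") else np.asarray(rec)

    def _loss_and_grad(self, model, xb, valid_mask, yb, training):
        logits = model.forward(xb, training=training)
        p = _nn.sigmoid(logits).astype(np.float64)
        pooled, dP_dp = _pooled_and_grad(p, valid_mask)
        pc = np.clip(pooled, 1e-7, 1.0 - 1e-7)
        loss = float(np.mean(-(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))))
        if not training:
            return loss, None
        dL_dP = (pc - yb) / (pc * (1.0 - pc)) / len(yb)
        grad_p = dL_dP[:, None] * dP_dp
        grad_logits = (grad_p * p * (1.0 - p)).astype(np.float32)
        return loss, grad_logits

    def fit(self, recordings, y=None):
        if y is None:
            labels = [rec.murmur_label for rec in recordings]
            keep = [i for i, lab in enumerate(labels) if lab != "Unknown"]
            recordings = [recordings[i] for i in keep]
            y = np.array([labels[i] == "Present" for i in keep], dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both bag classes")
        rng = np.random.default_rng(self.random_state)
        model = MILUNet(self.base_channels, self.depth, self.kernel_size,
                        seed=int(rng.integers(2 ** 31)))
        bags, lengths = [], []
        for rec in recordings:
            xb, n_valid = _prepare_bag(self._samples_of(rec), self.fixed_length)
            bags.append(xb)
            lengths.append(n_valid)
        X = np.stack(bags)
        valid = np.arange(self.fixed_length)[None, :] < np.asarray(lengths)[:, None]

        # stratified inner validation split
        idx = np.arange(len(y))
        val_idx = []
        for cls in (0.0, 1.0):
            cls_idx = idx[y == cls]
            cls_idx = cls_idx[rng.permutation(len(cls_idx))]
            n_val = max(1, int(round(self.val_fraction * len(cls_idx))))
            val_idx += list(cls_idx[:n_val])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        tr_idx, va_idx = idx[~val_mask], idx[val_mask]

        opt = _nn.Adam(model.parameters(), lr=self.lr)
        history = {"train_loss": [], "val_loss": []}
        best_state, best_val, since_best = model.state_dict(), np.inf, 0
        for epoch in range(self.epochs):
            opt.lr = self.lr * (self.lr_decay ** (epoch // self.lr_step_epochs))
            order = tr_idx[rng.permutation(len(tr_idx))]
            ep_losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                xb = X[batch][:, None, :]
                opt.zero_grad()
                loss, grad_logits = self._loss_and_grad(
                    model, xb, valid[batch], y[batch], training=True)
                model.backward(grad_logits)
                opt.step()
                ep_losses.append(loss)
            val_losses = []
            for start in range(0, len(va_idx), self.batch_size):
                batch = va_idx[start:start + self.batch_size]
                loss, _ = self._loss_and_grad(
                    model, X[batch][:, None, :], valid[batch], y[batch],
                    training=False)
                val_losses.append(loss * len(batch))
            val_loss = float(np.sum(val_losses) / len(va_idx))
            history["train_loss"].append(float(np.mean(ep_losses)))
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val, best_state, since_best = val_loss, model.state_dict(), 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if self.epochs > 0:
            model.load_state(best_state)
        self.model_ = model
        self.history_ = history
        return self

    def murmurness(self, samples) -> np.ndarray:
        return murmurness(self.model_, self._samples_of(samples))

    def predict_proba(self, recordings) -> np.ndarray:
        return np.array([bag_probability(self.model_, self._samples_of(r))
                         for r in recordings])

    def predict(self, recordings) -> np.ndarray:
        return (self.predict_proba(recordings) >= 0.5).astype(int)

    def segments(self, samples, rate: float) -> list[MurmurSegment]:
        return postprocess(self.murmurness(samples), rate,
                           self.threshold, self.merge_ms)

    def explain(self, recording, rate: float | None = None,
                segmentation: PhaseSegmentation | None = None,
                murmur_phase: str = "systolic") -> dict:
        """Murmurness trace, murmur segments and (if possible) phase precision."""
        rate = rate or getattr(recording, "sampling_rate", None)
        if rate is None:
            raise ValueError("sampling rate required")
        segmentation = segmentation if segmentation is not None \
            else getattr(recording, "segmentation", None)
        trace = self.murmurness(recording)
        segs = postprocess(trace, rate, self.threshold, self.merge_ms)
        out = {"trace": trace, "segments": segs, "precision": None}
        if segmentation is not None:
            out["precision"] = phase_precision(segs, segmentation, murmur_phase)
        return out


def train_mil(recordings, y=None, config: MILTrainConfig | None = None,
              seed: int = 0, **overrides) -> tuple[MILUNet, dict]:
    """Functional wrapper over :class:`MILUNetDetector`."""
    cfg = config or MILTrainConfig()
    det = MILUNetDetector(
        epochs=overrides.pop("epochs", cfg.epochs),
        batch_size=cfg.batch_size, lr=cfg.lr, lr_decay=cfg.lr_decay,
        lr_step_epochs=cfg.lr_step_epochs, fixed_length=cfg.fixed_length,
        val_fraction=cfg.val_fraction, patience=cfg.patience,
        random_state=seed, **overrides)
    det.fit(recordings, y)
    return det.model_, det.history_
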