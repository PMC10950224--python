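"""Reference synthetic experiments exercising the full stack.

Two canonical study conditions are fixed here and reused by the test suite
and the reproduction script:

* **MIL localization**: train the MIL U-Net on 240 recordings of 8.192 s
  (2^14 samples at 2 kHz) — half with a systolic murmur at +6 dB SNR in the
  200-450 Hz band, half murmur-free — then score murmur localisation on 40
  held-out recordings: phase precision on the murmur half, the
  no-activation rate on the murmur-free half, and bag-level accuracy.

* **Two-stage recovery**: on a separable three-class cohort (Present =
  strong murmur, Unknown = faint murmur in heavy noise, Absent = clean),
  train the handcrafted-feature selection, the PANN feature generator and
  the stage-2 multitask classifier on 60 patients and evaluate weighted
  accuracy, outcome cost and ranking metrics on 30 held-out patients.

Problem sizes are chosen so each experiment runs in a few minutes on one
CPU while leaving clear margins on the expected effects.
"""

from __future__ import annotations

import numpy as np

from .metrics import standard_metrics
from .mil import MILUNetDetector, NO_ACTIVATION, phase_precision, postprocess
from .pipeline import RunConfig, run_two_stage
from .simulate import CohortConfig, SimConfig, synth_cohort, synth_recording

# conditions of the separable two-stage cohort
SEPARABLE_COHORT = CohortConfig(
    class_probs=(0.34, 0.22, 0.44),
    duration=4.096,
    present_snr_range=(9.0, 12.0),
    unknown_snr_range=(-3.0, 0.0),
    unknown_noise_range=(0.25, 0.4),
    absent_noise_range=(0.01, 0.04),
)


def _mil_recordings(n, seed0, murmur, rng):
    recs = []
    for i in range(n):
        recs.append(synth_recording(SimConfig(
            heart_rate=float(rng.uniform(70.0, 140.0)),
            murmur_present=murmur, murmur_snr=6.0,
            noise_level=float(rng.uniform(0.01, 0.05)),
            seed=seed0 + i)))
    return recs


def mil_localization_experiment(seed: int = 0, n_train_per_class: int = 120,
                                n_heldout_per_class: int = 20,
                                epochs: int = 20,
                                batch_size: int = 16) -> dict:
    """Train the MIL U-Net and quantify held-out murmur localisation."""
    root = np.random.default_rng(seed)
    offsets = root.integers(0, 2 ** 24, size=4)
    rng = np.random.default_rng(seed + 1)
    train = (_mil_recordings(n_train_per_class, int(offsets[0]), True, rng)
             + _mil_recordings(n_train_per_class, int(offsets[1]), False, rng))
    held_murmur = _mil_recordings(n_heldout_per_class, int(offsets[2]), True, rng)
    held_absent = _mil_recordings(n_heldout_per_class, int(offsets[3]), False, rng)

    detector = MILUNetDetector(epochs=epochs, batch_size=batch_size,
                               random_state=seed)
    detector.fit(train)

    precisions = []
    for rec in held_murmur:
        segments = postprocess(detector.murmurness(rec.samples),
                               rec.sampling_rate)
        precisions.append(phase_precision(segments, rec.segmentation,
                                          "systolic"))
    numeric = [p for p in precisions if p != NO_ACTIVATION]
    n_no_act_absent = sum(
        1 for rec in held_absent
        if not postprocess(detector.murmurness(rec.samples), rec.sampling_rate))

    probs = detector.predict_proba(held_murmur + held_absent)
    truth = np.array([1] * len(held_murmur) + [0] * len(held_absent))
    bag_metrics = standard_metrics(probs, truth)
    return {
        "median_phase_precision": float(np.median(numeric)) if numeric
        else float("nan"),
        "n_scored_murmur_recordings": len(numeric),
        "no_activation_rate_absent": n_no_act_absent / len(held_absent),
        "bag_accuracy": bag_metrics["accuracy"],
        "bag_auroc": bag_metrics["auroc"],
        "final_train_loss": detector.history_["train_loss"][-1],
        "detector": detector,
    }


def selection_experiment(seed: int = 0, n_recordings: int = 80):
    """Importance-based feature selection on a varied synthetic table.

    Murmurs span the four shapes, SNRs from faint (-2 dB) to clear (+6 dB)
    and noisy backgrounds, so no single feature separates the classes and
    the gain ranking spreads over many features.
    """
    import pandas as pd

    from . import features as ft

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    shapes = ("diamond", "plateau", "crescendo", "decrescendo")
    for i in range(n_recordings):
        murmur = i % 2 == 0
        rec = synth_recording(SimConfig(
            duration=4.096, heart_rate=float(rng.uniform(80.0, 140.0)),
            murmur_present=murmur, murmur_snr=float(rng.uniform(-2.0, 6.0)),
            murmur_shape=shapes[i % 4],
            noise_level=float(rng.uniform(0.05, 0.2)),
            seed=seed * 1000 + i))
        rows.append(ft.extract_features(rec.samples, rec.sampling_rate,
                                        rec.segmentation, rec.demographics))
        labels.append(int(murmur))
    table = pd.DataFrame(rows).reset_index(drop=True)
    return ft.rank_and_select(table, labels, k=20, seed=seed)


def two_stage_experiment(seed: int = 0, n_train: int = 60,
                         n_test: int = 30) -> dict:
    """Train and evaluate the full two-stage pipeline on a separable cohort."""
    train = synth_cohort(n_train, SEPARABLE_COHORT, seed=seed)
    test = synth_cohort(n_test, SEPARABLE_COHORT, seed=seed + 10_000)
    cfg = RunConfig(pann_epochs=30, stage2_epochs=200)
    return run_two_stage(train, test, cfg, seed=seed)
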