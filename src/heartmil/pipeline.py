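"""End-to-end orchestration: two-stage training, evaluation, cross-validation.

The canonical run trains the PANN feature generator and the handcrafted
feature selection on the training patients' recordings, assembles one fused
feature vector per patient, trains the stage-2 multitask classifier and
evaluates murmur weighted accuracy, outcome cost and ranking metrics on
held-out patients.  Cross-validation splits patients (never recordings)
into stratified folds.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import HandcraftedFeatureExtractor, ImportanceFeatureSelector
from .metrics import (MurmurConfusion, OutcomeCounts, multiclass_metrics,
                      outcome_cost, standard_metrics, weighted_accuracy)
from .mil import MILUNetDetector, phase_precision, postprocess
from .pann import PANNFeatureGenerator
from .stage2 import (MURMUR_ORDER, OUTCOME_ORDER, PatientMultitaskClassifier,
                     assemble_patient_features)


@dataclass(frozen=True)
class RunConfig:
    folds: int = 10
    val_fraction: float = 0.2
    seed: int = 0
    selector_k: int = 20
    pann_epochs: int = 40
    stage2_epochs: int = 300

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TwoStageModel:
    extractor: HandcraftedFeatureExtractor
    selector: ImportanceFeatureSelector
    pann: PANNFeatureGenerator
    stage2: PatientMultitaskClassifier
    feature_names: list[str] = field(default_factory=list)


def _patient_rows(patients, extractor, selector, pann):
    """Assemble the fused stage-2 feature matrix, one row per patient."""
    rows, names = [], None
    for patient in patients:
        table = extractor.transform(patient.recordings)
        selected = selector.transform(table).mean(axis=0)
        preds = {rec.location: pann.predict_recording(rec)
                 for rec in patient.recordings}
        fs = assemble_patient_features(patient, preds, selected)
        rows.append(fs.vector)
        names = fs.names
    return np.stack(rows), names


def fit_two_stage(train_patients, config: RunConfig | None = None,
                  seed: int = 0) -> TwoStageModel:
    cfg = config or RunConfig()
    root = np.random.SeedSequence(seed)
    s_sel, s_pann, s_stage2 = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in root.spawn(3)]
    recordings = [rec for p in train_patients for rec in p.recordings]
    extractor = HandcraftedFeatureExtractor().fit(recordings)
    rec_table = extractor.transform(recordings)
    rec_labels = np.array([rec.murmur_label == "Present" for rec in recordings])
    known = np.array([rec.murmur_label != "Unknown" for rec in recordings])
    selector = ImportanceFeatureSelector(k=cfg.selector_k, seed=s_sel)
    selector.fit(rec_table[known], rec_labels[known].astype(int))
    pann = PANNFeatureGenerator(epochs=cfg.pann_epochs, random_state=s_pann)
    pann.fit(recordings)
    X, names = _patient_rows(train_patients, extractor, selector, pann)
    stage2 = PatientMultitaskClassifier(epochs=cfg.stage2_epochs,
                                        random_state=s_stage2)
    stage2.fit(X, [p.murmur_label for p in train_patients],
               [p.outcome_label for p in train_patients])
    return TwoStageModel(extractor, selector, pann, stage2, names)


def predict_two_stage(model: TwoStageModel, patients):
    X, _ = _patient_rows(patients, model.extractor, model.selector, model.pann)
    pm, po = model.stage2.predict_proba(X)
    murmur = [MURMUR_ORDER[i] for i in pm.argmax(axis=1)]
    outcome = [OUTCOME_ORDER[i] for i in po.argmax(axis=1)]
    return {"murmur_probs": pm, "outcome_probs": po,
            "murmur_labels": murmur, "outcome_labels": outcome}


def evaluate_predictions(predictions, patients) -> dict[str, float]:
    true_m = [p.murmur_label for p in patients]
    true_o = [p.outcome_label for p in patients]
    conf = MurmurConfusion.from_labels(predictions["murmur_labels"], true_m,
                                       classes=("Present", "Unknown", "Absent"))
    # reorder probability columns (Absent, Unknown, Present) -> (P, U, A)
    pm = predictions["murmur_probs"][:, ::-1]
    out = {"murmur_weighted_accuracy": weighted_accuracy(conf)}
    out.update({f"murmur_{k}": v for k, v in multiclass_metrics(
        pm, true_m, classes=("Present", "Unknown", "Absent")).items()})
    counts = OutcomeCounts.from_labels(predictions["outcome_labels"], true_o)
    out["outcome_cost"] = outcome_cost(counts)
    out.update({f"outcome_{k}": v for k, v in standard_metrics(
        predictions["outcome_probs"][:, 1],
        [t == "Abnormal" for t in true_o]).items()})
    return out


def run_two_stage(train_patients, test_patients,
                  config: RunConfig | None = None, seed: int = 0) -> dict[str, float]:
    model = fit_two_stage(train_patients, config, seed)
    return evaluate_predictions(predict_two_stage(model, test_patients),
                                test_patients)


def stratified_patient_folds(patients, n_folds: int, seed: int = 0,
                             max_retries: int = 20) -> list[np.ndarray]:
    """Disjoint patient-level folds, stratified by murmur label.

    If some fold's training complement lacks a murmur class the split is
    resampled with a warning.
    """
    labels = [p.murmur_label for p in patients]
    classes = sorted(set(labels))
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        offset = 0
        for cls in classes:
            idx = [i for i, lab in enumerate(labels) if lab == cls]
            idx = list(rng.permutation(idx))
            for j, i in enumerate(idx):
                folds[(offset + j) % n_folds].append(i)
            offset += len(idx)
        ok = all(
            set(classes) <= {labels[i] for f2, fold2 in enumerate(folds)
                             for i in fold2 if f2 != f}
            for f in range(n_folds))
        if ok:
            return [np.array(sorted(f)) for f in folds]
        warnings.warn("a fold's training portion lacked a class; resampling split")
    raise ValueError("could not build stratified folds with all classes")


def cross_validate(patients, config: RunConfig | None = None,
                   train_eval_fn=None) -> dict:
    """Patient-level stratified k-fold evaluation.

    ``train_eval_fn(train_patients, test_patients, seed) -> dict`` defaults
    to the full two-stage pipeline; injectable for cheap models.
    """
    cfg = config or RunConfig()
    if len(patients) < cfg.folds:
        raise ValueError("need at least as many patients as folds")
    fn = train_eval_fn or (lambda tr, te, seed: run_two_stage(tr, te, cfg, seed))
    folds = stratified_patient_folds(patients, cfg.folds, cfg.seed)
    per_fold = []
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train = [p for i, p in enumerate(patients) if i not in test_set]
        test = [patients[i] for i in sorted(test_set)]
        per_fold.append(fn(train, test, cfg.seed + f))
    keys = sorted({k for fold in per_fold for k in fold})
    agg = {}
    for k in keys:
        vals = np.array([fold[k] for fold in per_fold if k in fold], dtype=float)
        agg[k] = {"mean": float(np.nanmean(vals)), "std": float(np.nanstd(vals))}
    return {"per_fold": per_fold, "aggregate": agg, "folds": folds}


def run_explain(samples, rate, detector: MILUNetDetector,
                segmentation=None, murmur_phase: str = "systolic") -> dict:
    """Murmurness trace, postprocessed segments and per-phase precision."""
    trace = detector.murmurness(samples)
    segments = postprocess(trace, rate, detector.threshold, detector.merge_ms)
    report = {"trace": trace, "segments": segments, "precision": None}
    if segmentation is not None:
        report["precision"] = phase_precision(segments, segmentation, murmur_phase)
    return report


def timed(fn, *args, **kwargs):
    t0 = time.perf_counter()
    result = fn(*args, **kwargs)
    return result, time.perf_counter() - t0
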