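"""Metrics and experiment drivers.

Prediction-quality metrics for the continuous angle output (Pearson R, RMSE,
NRMSE), classification metrics for gait phases (accuracy, confusion matrix,
per-phase accuracy), a one-way ANOVA from closed-form sums of squares, the
modified leave-one-out cross-validation protocol (test one trial of one
subject; train on that subject's remaining trials plus everyone else's), and
the two cross-condition experiments: degradation (train/test across the
exoskeleton conditions) and adaptation (fine-tuning on growing budgets of
shifted-condition data).

NRMSE is normalised by the range of the *predicted* trace (a
reference-range variant is available via ``use_reference_range``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from . import models as _models
from .features import FeatureFrame
from .simulate import PHASES


def pearson_r(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pearson correlation cov(pred, ref) / (sigma_pred * sigma_ref).

    Population (1/n) convention throughout; the choice cancels between
    numerator and denominator.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise ValueError("inputs must be equal-length with at least 2 samples")
    dp = pred - pred.mean()
    dr = ref - ref.mean()
    sp = np.sqrt(np.mean(dp * dp))
    sr = np.sqrt(np.mean(dr * dr))
    if sp == 0 or sr == 0:
        raise ValueError("zero variance: Pearson R undefined for constant input")
    return float(np.mean(dp * dr) / (sp * sr))


def rmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root mean square error sqrt(mean (pred - ref)^2)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 1:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def nrmse(pred: np.ndarray, ref: np.ndarray, use_reference_range: bool = False) -> float:
    """RMSE normalised by the predicted trace's range (fraction, not %)."""
    base = np.asarray(ref if use_reference_range else pred, dtype=float)
    rng = float(np.ptp(base))
    if rng == 0:
        raise ValueError("zero range: NRMSE undefined for constant trace")
    return rmse(pred, ref) / rng


def confusion_matrix(y_true, y_pred, n_classes: int = 4) -> np.ndarray:
    """Counts with true phase on rows, predicted phase on columns."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from closed-form between/within sums of squares.

    Returns (F, p). Identical groups give F = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        f_stat = 0.0 if msb == 0 else np.inf
    else:
        f_stat = max(msb / msw, 0.0)
    p = float(_stats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p


@dataclass
class MetricsReport:
    """Classification and/or regression metrics for one evaluation."""

    n: int = 0
    fold_id: str = ""
    acc: float | None = None
    confusion: np.ndarray | None = None
    per_phase_acc: np.ndarray | None = None
    r_value: float | None = None
    rmse: float | None = None
    nrmse: float | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_classification(cls, y_true, y_pred, fold_id: str = "") -> "MetricsReport":
        cm = confusion_matrix(y_true, y_pred)
        totals = cm.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_phase = np.where(totals > 0, np.diag(cm) / np.maximum(totals, 1), np.nan)
        return cls(
            n=int(cm.sum()),
            fold_id=fold_id,
            acc=float(np.trace(cm) / cm.sum()),
            confusion=cm,
            per_phase_acc=per_phase,
        )

    @classmethod
    def from_regression(cls, pred, ref, fold_id: str = "") -> "MetricsReport":
        return cls(
            n=len(np.asarray(pred)),
            fold_id=fold_id,
            r_value=pearson_r(pred, ref),
            rmse=rmse(pred, ref),
            nrmse=nrmse(pred, ref),
        )


def loo_folds(items_by_subject: Mapping[str, Sequence]) -> list[dict]:
    """Folds of the modified leave-one-out protocol.

    Each fold tests one trial of one subject and trains on that subject's
    other trials plus all trials of all other subjects; every trial is tested
    exactly once.
    """
    subjects = list(items_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    for s in subjects:
        if len(items_by_subject[s]) < 2:
            raise ValueError(f"subject '{s}' has fewer than 2 trials")
    folds = []
    for s in subjects:
        for i, item in enumerate(items_by_subject[s]):
            train = [t for j, t in enumerate(items_by_subject[s]) if j != i]
            for other in subjects:
                if other != s:
                    train.extend(items_by_subject[other])
            folds.append({"fold_id": f"{s}/{i}", "test": item, "train": train})
    return folds


def loo_cv(
    items_by_subject: Mapping[str, Sequence],
    run_fold: Callable[[list, object, str], MetricsReport],
) -> list[MetricsReport]:
    """Run ``run_fold(train_items, test_item, fold_id)`` over every fold."""
    return [
        run_fold(f["train"], f["test"], f["fold_id"])
        for f in loo_folds(items_by_subject)
    ]


def classifier_loo_cv(
    frames_by_subject: Mapping[str, Sequence[FeatureFrame]], **clf_params
) -> list[MetricsReport]:
    """Leave-one-out CV of the phase classifier over feature frames."""

    def run(train, test, fold_id):
        clf = _models.train_phase_classifier(list(train), **clf_params)
        pred, _ = _models.classify(clf, test)
        return MetricsReport.from_classification(test.phase, pred, fold_id)

    return loo_cv(frames_by_subject, run)


def _split_frame(frame: FeatureFrame, train_fraction: float = 0.7):
    cut = int(train_fraction * len(frame))
    return frame.slice(0, cut), frame.slice(cut, len(frame))


def degradation_experiment(
    frame_noexo: FeatureFrame,
    frame_exo: FeatureFrame,
    train_fraction: float = 0.7,
    clf_params: dict | None = None,
    pred_params: dict | None = None,
    include_predictor: bool = True,
) -> dict:
    """All four train->test condition combinations for classifier (and predictor).

    Each condition's frame is split chronologically into a training portion and
    a held-out tail; a model trained on one condition is evaluated on the
    held-out tails of both. The angle predictor is evaluated with true phase
    labels as its phase input (isolating the effect of the signal shift).
    Returns {'classifier': {(train, test): MetricsReport}, 'predictor': ...}.
    """
    clf_params = clf_params or {}
    pred_params = pred_params or {}
    conditions = {"noExo": frame_noexo, "exo": frame_exo}
    splits = {c: _split_frame(f, train_fraction) for c, f in conditions.items()}
    out: dict = {"classifier": {}, "predictor": {}}
    for c_train, (tr, _) in splits.items():
        clf = _models.train_phase_classifier(tr, **clf_params)
        for c_test, (_, te) in splits.items():
            pred, _p = _models.classify(clf, te)
            out["classifier"][(c_train, c_test)] = (
                MetricsReport.from_classification(te.phase, pred,
                                                  f"{c_train}->{c_test}")
            )
    if include_predictor:
        for c_train, (tr, _) in splits.items():
            reg = _models.train_angle_predictor(tr, **pred_params)
            for c_test, (_, te) in splits.items():
                yhat = _models.predict_ahead(reg, te, "true_labels")
                out["predictor"][(c_train, c_test)] = (
                    MetricsReport.from_regression(yhat, te.angle_future,
                                                  f"{c_train}->{c_test}")
                )
    return out


def adaptation_curve(
    frame_noexo: FeatureFrame,
    frame_exo: FeatureFrame,
    minutes: Sequence[float] = (0, 1, 2, 3, 4),
    task: str = "phase",
    fine_tune_lr: float = 1e-4,
    fine_tune_epochs: int = 10,
    clf_params: dict | None = None,
    pred_params: dict | None = None,
) -> dict:
    """Fine-tuning recovery curve after the exoskeleton-induced shift.

    A base model trained on the no-exoskeleton frame is adapted on growing
    prefixes of the exoskeleton frame; data beyond the largest budget is the
    fixed test set. The 'ceiling' entry retrains a fresh model on the full
    adaptation pool (the within-condition reference the curve should
    approach). ``task`` is 'phase' or 'angle'.
    """
    windows_per_min = 60000.0 / frame_exo.increment_ms
    if task == "phase":
        params = clf_params or {}
        base = _models.train_phase_classifier(frame_noexo, **params)
        X_new, y_new = frame_exo.X, frame_exo.phase

        def metric(m, X, y):
            return MetricsReport.from_classification(y, m.predict(X))

    elif task == "angle":
        params = pred_params or {}
        base = _models.train_angle_predictor(frame_noexo, **params)
        X_new = _models.assemble_predictor_inputs(frame_exo, base.input_mode)
        y_new = frame_exo.angle_future

        def metric(m, X, y):
            return MetricsReport.from_regression(m.predict(X), y)

    else:
        raise ValueError("task must be 'phase' or 'angle'")

    adapted, curve, (X_test, y_test) = _models.fine_tune(
        base, X_new, y_new, list(minutes),
        windows_per_min=windows_per_min,
        lr=fine_tune_lr, epochs=fine_tune_epochs, metric_fn=metric,
    )
    max_w = int(round(max(minutes) * windows_per_min))
    if task == "phase":
        ceiling_model = _models.GaitPhaseClassifier(**(clf_params or {}))
        ceiling_model.fit(X_new[:max_w], y_new[:max_w])
    else:
        ceiling_model = _models.AnkleAnglePredictor(
            input_mode=base.input_mode,
            **{k: v for k, v in (pred_params or {}).items() if k != "input_mode"},
        )
        ceiling_model.fit(X_new[:max_w], y_new[:max_w])
    ceiling = metric(ceiling_model, X_test, y_test)
    return {
        "minutes": sorted(minutes),
        "reports": curve,
        "ceiling": ceiling,
        "models": adapted,
    }


def curve_table(result: dict, task: str = "phase"):
    """Adaptation curve as a tidy DataFrame (budget_min, metric, value)."""
    import pandas as pd

    rows = []
    for m, rep in zip(result["minutes"], result["reports"]):
        if task == "phase":
            rows.append({"budget_min": m, "metric": "acc", "value": rep.acc})
            for p, v in zip(PHASES, rep.per_phase_acc):
                rows.append({"budget_min": m, "metric": f"acc_{p}", "value": v})
        else:
            for name in ("r_value", "rmse", "nrmse"):
                rows.append({"budget_min": m, "metric": name,
                             "value": getattr(rep, name)})
    return pd.DataFrame(rows)
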