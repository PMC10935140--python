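"""Subject-disjoint evaluation of fall detectors.

Windows cut from the same person's trials are strongly correlated, so all
cross-validation here is grouped at the (dataset, subject) level: every
subject's windows live in exactly one fold.  Metrics are chosen for the
imbalanced setting — recall (sensitivity), specificity, precision, F1,
accuracy, AUC-ROC, and maxSeSp, the best balanced operating point
max over thresholds of min(sensitivity, specificity).

Three experiment designs are provided as drivers over a corpus feature
matrix: within-dataset grouped k-fold, combined-corpus grouped k-fold, and
cross-dataset generalization (train on one source, a single evaluation on
the pooled held-out sources).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import models as _models
from . import selection as _selection
from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

METRIC_NAMES = ("recall", "specificity", "precision", "f1", "accuracy",
                "auc_roc", "max_sesp")


# ---------------------------------------------------------------------------
# grouped k-fold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Partition of subject keys into k folds (fold ids 0..k-1)."""

    k: int
    mapping: dict[tuple, int]

    def fold_of(self, subject_keys) -> np.ndarray:
        return np.array([self.mapping[k] for k in subject_keys])

    def subjects_in(self, fold: int) -> set[tuple]:
        return {s for s, f in self.mapping.items() if f == fold}


def subject_group_kfold(subject_keys, k: int, seed: int = 0,
                        y=None, max_retries: int = 100) -> FoldAssignment:
    """Deal shuffled subjects round-robin into k subject-disjoint folds.

    ``subject_keys`` is a per-row sequence of hashable (dataset, subject)
    keys; distinct keys are shuffled with ``seed`` and dealt round-robin.
    When per-row labels ``y`` are given, shuffling is retried (bounded by
    ``max_retries``) until every fold's test split contains both classes,
    if such an assignment is found.
    """
    keys = [tuple(key) if isinstance(key, (list, np.ndarray)) else key
            for key in subject_keys]
    subjects = sorted(set(keys))
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(subjects) < k:
        raise ValueError(
            f"only {len(subjects)} distinct subjects for k={k}; "
            f"use a smaller k")
    rng = np.random.default_rng(seed)
    y = None if y is None else np.asarray(y)
    rows_of: dict[tuple, np.ndarray] = {}
    if y is not None:
        for s in subjects:
            rows_of[s] = np.flatnonzero([kk == s for kk in keys])
    assignment = None
    for _ in range(max_retries):
        order = list(subjects)
        rng.shuffle(order)
        mapping = {s: i % k for i, s in enumerate(order)}
        assignment = FoldAssignment(k=k, mapping=mapping)
        if y is None:
            return assignment
        ok = True
        for fold in range(k):
            test_rows = np.concatenate(
                [rows_of[s] for s in subjects if mapping[s] == fold])
            if np.unique(y[test_rows]).size < 2:
                ok = False
                break
        if ok:
            return assignment
    logger.warning("no fold assignment with both classes in every test "
                   "split found in %d retries; using the last one",
                   max_retries)
    return assignment


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Recall, specificity, precision, F1 and accuracy (fall = positive).

    Ratios with zero denominators are reported as 0 with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); "
                          f"reporting 0", stacklevel=3)
            return 0.0
        return num / den

    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    f1 = (0.0 if precision + recall == 0
          else 2 * precision * recall / (precision + recall))
    return {"recall": recall, "specificity": specificity,
            "precision": precision, "f1": f1,
            "accuracy": (tp + tn) / y_true.size}


def _require_both_classes(y_true: np.ndarray) -> None:
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present in y_true")


def roc_auc(y_true, scores) -> float:
    """Probability a random fall outscores a random ADL window (ties 1/2)."""
    y_true = np.asarray(y_true).astype(int)
    _require_both_classes(y_true)
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def max_sesp(y_true, scores) -> float:
    """Best balanced operating point: max over thresholds of min(Se, Sp)."""
    y_true = np.asarray(y_true).astype(int)
    _require_both_classes(y_true)
    # keep every realizable threshold: the balanced point can sit at an
    # operating point the ROC convex-hull simplification would drop
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    return float(np.max(np.minimum(tpr, 1.0 - fpr)))


def _evaluate_predictions(y_true, y_pred, scores) -> dict[str, float]:
    out = confusion_metrics(y_true, y_pred)
    try:
        out["auc_roc"] = roc_auc(y_true, scores)
        out["max_sesp"] = max_sesp(y_true, scores)
    except ValueError:
        warnings.warn("single-class test split: AUC and maxSeSp recorded "
                      "as missing", stacklevel=2)
        out["auc_roc"] = np.nan
        out["max_sesp"] = np.nan
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold and aggregated metrics for one experiment."""

    descriptor: dict
    fold_metrics: pd.DataFrame
    fold_test_subjects: list[list[tuple]] = field(default_factory=list)

    @property
    def aggregates(self) -> pd.DataFrame:
        """Mean and std per metric across folds (missing entries excluded)."""
        rows = {}
        for m in METRIC_NAMES:
            vals = self.fold_metrics[m].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rows[m] = {"mean": vals.mean() if vals.size else np.nan,
                       "std": vals.std(ddof=0) if vals.size else np.nan,
                       "n_folds": int(vals.size)}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        agg = self.aggregates
        lines = [f"experiment: {self.descriptor}"]
        for m in METRIC_NAMES:
            lines.append(f"  {m:12s} {100 * agg.loc[m, 'mean']:6.2f} "
                         f"± {100 * agg.loc[m, 'std']:5.2f} %")
        return "\n".join(lines)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "descriptor": self.descriptor,
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
            "aggregates": {m: {k: (None if not np.isfinite(v) else v)
                               for k, v in row.items()}
                           for m, row in
                           self.aggregates.to_dict(orient="index").items()},
            "fold_test_subjects": [[list(s) for s in fold]
                                   for fold in self.fold_test_subjects],
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


# ---------------------------------------------------------------------------
# experiment configuration and helpers
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Shared knobs of the experiment drivers."""

    k: int = 10
    seed: int = 0
    weight_scheme: str = "inverse_frequency"
    svm_params: dict = field(default_factory=dict)
    ann_params: dict = field(default_factory=dict)
    run_selection: bool = True
    selection_params: dict = field(default_factory=dict)
    #: precomputed feature subset; skips the selection stage when given
    selected_features: list[str] | None = None


def _subject_keys(frame: pd.DataFrame) -> list[tuple]:
    return list(zip(frame["dataset"], frame["subject"]))


def _select(frame: pd.DataFrame, config: ExperimentConfig) -> list[str]:
    if config.selected_features is not None:
        return list(config.selected_features)
    if not config.run_selection:
        return list(FEATURE_COLUMNS)
    report = _selection.select_features(
        frame[list(FEATURE_COLUMNS)], frame["label"].to_numpy(),
        groups=_subject_keys(frame), seed=config.seed,
        **config.selection_params)
    return report.selected


def _fit(model_kind: str, X: pd.DataFrame, y: np.ndarray,
         selected: list[str],
         config: ExperimentConfig) -> _models.TrainedModel:
    weights = _models.compute_class_weights(y, scheme=config.weight_scheme)
    if model_kind == "svm":
        return _models.train_weighted_svm(
            X[selected], y, weights=weights, seed=config.seed,
            **config.svm_params)
    if model_kind == "ann":
        return _models.train_weighted_ann(
            X[selected], y, weights=weights, seed=config.seed,
            **config.ann_params)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _effective_k(n_subjects: int, k: int) -> int:
    if n_subjects < k:
        logger.warning("only %d subjects; reducing k from %d", n_subjects, k)
        return n_subjects
    return k


def _run_grouped_cv(frame: pd.DataFrame, model_kind: str,
                    config: ExperimentConfig,
                    descriptor: dict) -> EvalReport:
    selected = _select(frame, config)
    keys = _subject_keys(frame)
    y = frame["label"].to_numpy()
    k = _effective_k(len(set(keys)), config.k)
    assignment = subject_group_kfold(keys, k, seed=config.seed, y=y)
    folds = assignment.fold_of(keys)
    rows = []
    fold_subjects = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        model = _fit(model_kind, frame.loc[train], y[train], selected,
                     config)
        scores = model.decision_scores(frame.loc[test])
        y_pred = model.predict(frame.loc[test])
        metrics = _evaluate_predictions(y[test], y_pred, scores)
        metrics.update({"fold": fold, "n_test": int(test.sum())})
        rows.append(metrics)
        fold_subjects.append(sorted(assignment.subjects_in(fold)))
    descriptor = dict(descriptor, model_kind=model_kind, k=k,
                      seed=config.seed, selected_features=selected,
                      n_windows=int(len(frame)))
    return EvalReport(descriptor=descriptor,
                      fold_metrics=pd.DataFrame(rows),
                      fold_test_subjects=fold_subjects)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def run_within_dataset(features: pd.DataFrame, dataset: str,
                       model_kind: str,
                       config: ExperimentConfig | None = None) -> EvalReport:
    """Grouped k-fold CV on a single source (selection on that source)."""
    config = config or ExperimentConfig()
    frame = features[features["dataset"] == dataset].reset_index(drop=True)
    if frame.empty:
        raise ValueError(f"no windows for dataset {dataset!r}")
    return _run_grouped_cv(frame, model_kind, config,
                           {"experiment": "within_dataset",
                            "train_datasets": [dataset],
                            "test_datasets": [dataset]})


def run_combined(features: pd.DataFrame, model_kind: str,
                 config: ExperimentConfig | None = None,
                 datasets: list[str] | None = None,
                 normalization_mode: str = "off") -> EvalReport:
    """Grouped k-fold CV on the concatenated multi-source corpus."""
    config = config or ExperimentConfig()
    frame = features if datasets is None else \
        features[features["dataset"].isin(datasets)]
    frame = frame.reset_index(drop=True)
    dup_key = ["dataset", "subject", "activity", "trial", "window_index"]
    if frame.duplicated(subset=dup_key).any():
        raise ValueError("combined matrix has duplicate window keys")
    names = sorted(frame["dataset"].unique())
    return _run_grouped_cv(frame, model_kind, config,
                           {"experiment": "combined",
                            "train_datasets": names, "test_datasets": names,
                            "normalization": normalization_mode})


def run_cross_dataset(features: pd.DataFrame, train_dataset: str,
                      test_datasets: list[str], model_kind: str,
                      config: ExperimentConfig | None = None,
                      normalization_mode: str = "off") -> EvalReport:
    """Train on one source, evaluate once on the pooled held-out sources."""
    config = config or ExperimentConfig()
    if train_dataset in test_datasets:
        raise ValueError("train dataset must not appear among test datasets")
    if not test_datasets:
        raise ValueError("need at least one held-out dataset")
    train = features[features["dataset"] == train_dataset].reset_index(
        drop=True)
    test = features[features["dataset"].isin(test_datasets)].reset_index(
        drop=True)
    if train.empty or test.empty:
        raise ValueError("empty train or test partition")
    selected = _select(train, config)
    model = _fit(model_kind, train, train["label"].to_numpy(), selected,
                 config)
    scores = model.decision_scores(test)
    y_pred = model.predict(test)
    metrics = _evaluate_predictions(test["label"].to_numpy(), y_pred, scores)
    metrics.update({"fold": 0, "n_test": int(len(test))})
    descriptor = {"experiment": "cross_dataset",
                  "train_datasets": [train_dataset],
                  "test_datasets": sorted(test_datasets),
                  "normalization": normalization_mode,
                  "model_kind": model_kind, "k": 1, "seed": config.seed,
                  "selected_features": selected,
                  "n_windows": int(len(train) + len(test))}
    return EvalReport(descriptor=descriptor,
                      fold_metrics=pd.DataFrame([metrics]),
                      fold_test_subjects=[sorted(set(_subject_keys(test)))])


def run_threshold_baseline(recordings, threshold: float = 2.5,
                           spec=None) -> dict[str, float]:
    """Evaluate the magnitude-threshold detector on raw recordings.

    Returns the confusion metrics of the fixed-threshold operating point
    plus ``min_sesp`` (min of Se and Sp there) and the score-based
    ``max_sesp`` / ``auc_roc`` obtained by sweeping the threshold over the
    per-window peak norms.
    """
    from .features import WindowSpec, acc_norm_peaks
    spec = spec or WindowSpec()
    peaks, labels = [], []
    for rec in recordings:
        p, lab = acc_norm_peaks(rec, spec)
        peaks.append(p)
        labels.append(lab)
    peaks = np.concatenate(peaks)
    labels = np.concatenate(labels)
    y_pred = _models.threshold_baseline(peaks, threshold)
    out = confusion_metrics(labels, y_pred)
    out["min_sesp"] = min(out["recall"], out["specificity"])
    out["auc_roc"] = roc_auc(labels, peaks)
    out["max_sesp"] = max_sesp(labels, peaks)
    out["threshold_g"] = threshold
    out["n_windows"] = int(labels.size)
    return out
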