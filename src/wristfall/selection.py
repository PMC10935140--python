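"""Two-stage random-forest feature selection.

Stage 1 ranks all features by mean-decrease-in-impurity (Gini) importance
from a seeded random forest.  Stage 2 measures the marginal contribution of
each retained feature by one-at-a-time exclusion: the drop in
subject-disjoint cross-validated accuracy when the feature is removed from
the candidate set.  The selected subset is the intersection of both keep
rules, in ranking order.

Keep rules are plain strings:

* importance stage — ``"above_mean"`` (default), ``"top_k=K"`` or
  ``"min_importance=X"``;
* ablation stage — ``"keep_unless_harmful"`` (default: drop a feature
  only when its exclusion improves CV accuracy significantly, i.e. the mean
  exclusion delta is below -2 standard errors of the per-fold deltas;
  redundant features with a zero marginal delta are kept),
  ``"positive_delta"`` (strictly positive mean delta required),
  ``"nonnegative_delta"``, ``"delta_ge=X"`` or ``"all"`` (skip the
  ablation filter).

If the rules eliminate everything, the top-ranked feature is kept with a
warning.  Ties in importance break by feature-name lexicographic order so
selection is invariant to input column order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass
class SelectionReport:
    """Ranking, ablation deltas and the selected subset of one run."""

    gini_ranking: list[tuple[str, float]]
    ablation: list[tuple[str, float]]
    selected: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(imp for _, imp in self.gini_ranking)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("Gini importances must sum to 1")
        ranked = {name for name, _ in self.gini_ranking}
        if not self.selected or not set(self.selected) <= ranked:
            raise ValueError("selected must be a non-empty subset of the "
                             "ranked features")

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps({
            "gini_ranking": self.gini_ranking,
            "ablation": self.ablation,
            "selected": self.selected,
            "params": self.params,
        }, indent=2))

    @classmethod
    def from_json(cls, path: Path | str) -> "SelectionReport":
        d = json.loads(Path(path).read_text())
        return cls(gini_ranking=[tuple(t) for t in d["gini_ranking"]],
                   ablation=[tuple(t) for t in d["ablation"]],
                   selected=d["selected"], params=d["params"])

    def write_selected(self, path: Path | str) -> None:
        """Plain-text one-feature-per-line file for downstream training."""
        Path(path).write_text("\n".join(self.selected) + "\n")


def _as_frame(X) -> pd.DataFrame:
    """Coerce to a DataFrame in canonical (lexicographic) column order.

    Random-forest fits depend on column positions through feature
    subsampling, so a fixed canonical order makes ranking and selection
    invariant to the caller's column order."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"f{i:03d}" for i in range(X.shape[1])])
    return X[sorted(X.columns)]


def _check_labels(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes in y")


def rank_gini_importance(X, y, n_trees: int = 200,
                         seed: int = 0) -> list[tuple[str, float]]:
    """Features sorted by decreasing Gini importance (deterministic).

    Importances are scikit-learn's normalized mean decrease in impurity, so
    they sum to 1; ties break lexicographically by feature name.
    """
    frame = _as_frame(X)
    y = np.asarray(y)
    _check_labels(y)
    if not np.all(np.isfinite(frame.to_numpy(dtype=float))):
        raise ValueError("feature matrix contains non-finite values")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(frame.to_numpy(dtype=float), y)
    pairs = list(zip(frame.columns, forest.feature_importances_))
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def ablation_accuracy_deltas(X, y, groups, candidate_features,
                             cv_folds: int = 5, seed: int = 0,
                             n_trees: int = 100,
                             scoring: str = "accuracy",
                             return_fold_detail: bool = False):
    """One-at-a-time exclusion deltas under subject-disjoint CV.

    For each candidate f, delta = CV score with all candidates minus CV
    score with candidates \\ {f}; a positive delta means f contributes.
    ``scoring`` is ``"accuracy"`` (mirroring the selection stage's plain
    accuracy despite imbalance) or ``"balanced_accuracy"``.

    Returns a list of (feature, mean delta) pairs; with
    ``return_fold_detail`` also a dict mapping each feature to its
    per-fold delta array, the yardstick for judging whether a delta is
    distinguishable from fold noise.
    """
    from .evaluation import subject_group_kfold  # deferred: avoids a cycle

    candidates = list(candidate_features)
    if not candidates:
        raise ValueError("candidate feature set must not be empty")
    frame = _as_frame(X)
    y = np.asarray(y)
    _check_labels(y)
    keys = [tuple(g) if isinstance(g, (list, np.ndarray)) else g
            for g in groups]
    if len(set(keys)) < cv_folds:
        raise ValueError(f"only {len(set(keys))} subjects for "
                         f"{cv_folds}-fold ablation CV")
    assignment = subject_group_kfold(keys, cv_folds, seed=seed, y=y)
    folds = assignment.fold_of(keys)

    def _fold_scores(feature_set: list[str]) -> np.ndarray:
        Xs = frame[sorted(feature_set)].to_numpy(dtype=float)
        scores = []
        for fold in range(cv_folds):
            test = folds == fold
            if not feature_set:
                # empty set: the featureless majority-class predictor
                classes, counts = np.unique(y[~test], return_counts=True)
                pred = np.full(int(test.sum()),
                               classes[np.argmax(counts)])
            else:
                clf = RandomForestClassifier(n_estimators=n_trees,
                                             random_state=seed, n_jobs=1)
                clf.fit(Xs[~test], y[~test])
                pred = clf.predict(Xs[test])
            if scoring == "balanced_accuracy":
                rec = [np.mean(pred[y[test] == c] == c)
                       for c in np.unique(y[test])]
                scores.append(float(np.mean(rec)))
            else:
                scores.append(float(np.mean(pred == y[test])))
        return np.asarray(scores)

    full = _fold_scores(candidates)
    detail = {f: full - _fold_scores([g for g in candidates if g != f])
              for f in candidates}
    pairs = [(f, float(np.mean(d))) for f, d in detail.items()]
    return (pairs, detail) if return_fold_detail else pairs


def _apply_importance_rule(ranking: list[tuple[str, float]],
                           rule: str) -> list[str]:
    if rule == "above_mean":
        cutoff = np.mean([imp for _, imp in ranking])
        return [name for name, imp in ranking if imp > cutoff]
    if rule.startswith("top_k="):
        k = int(rule.split("=", 1)[1])
        return [name for name, _ in ranking[:k]]
    if rule.startswith("min_importance="):
        x = float(rule.split("=", 1)[1])
        return [name for name, imp in ranking if imp >= x]
    raise ValueError(f"unknown importance keep rule {rule!r}")


def _apply_ablation_rule(deltas: list[tuple[str, float]],
                         rule: str,
                         fold_detail: dict | None = None) -> set[str]:
    if rule == "all":
        return {name for name, _ in deltas}
    if rule == "keep_unless_harmful":
        if fold_detail is None:
            raise ValueError("keep_unless_harmful needs per-fold deltas")
        kept = set()
        for name, d in deltas:
            folds = fold_detail[name]
            se = (folds.std(ddof=1) / np.sqrt(folds.size)
                  if folds.size > 1 else 0.0)
            if d >= -2.0 * se:
                kept.add(name)
        return kept
    if rule == "positive_delta":
        return {name for name, d in deltas if d > 0}
    if rule == "nonnegative_delta":
        return {name for name, d in deltas if d >= 0}
    if rule.startswith("delta_ge="):
        x = float(rule.split("=", 1)[1])
        return {name for name, d in deltas if d >= x}
    raise ValueError(f"unknown ablation keep rule {rule!r}")


def select_features(X, y, groups, importance_keep_rule: str = "above_mean",
                    ablation_keep_rule: str = "keep_unless_harmful",
                    n_trees: int = 200, ablation_trees: int = 100,
                    ablation_folds: int = 5, scoring: str = "accuracy",
                    seed: int = 0) -> SelectionReport:
    """Full two-stage selection; deterministic given the seed."""
    ranking = rank_gini_importance(X, y, n_trees=n_trees, seed=seed)
    candidates = _apply_importance_rule(ranking, importance_keep_rule)
    if not candidates:
        candidates = [ranking[0][0]]
    if ablation_keep_rule == "all":
        deltas = [(name, float("nan")) for name in candidates]
        kept = set(candidates)
    else:
        deltas, fold_detail = ablation_accuracy_deltas(
            X, y, groups, candidates, cv_folds=ablation_folds, seed=seed,
            n_trees=ablation_trees, scoring=scoring,
            return_fold_detail=True)
        kept = _apply_ablation_rule(deltas, ablation_keep_rule,
                                    fold_detail)
    selected = [name for name in candidates if name in kept]
    if not selected:
        warnings.warn("keep rules eliminated every feature; falling back "
                      "to the top-ranked one")
        selected = [ranking[0][0]]
    return SelectionReport(
        gini_ranking=ranking, ablation=deltas, selected=selected,
        params={"n_trees": n_trees, "ablation_trees": ablation_trees,
                "ablation_folds": ablation_folds,
                "importance_keep_rule": importance_keep_rule,
                "ablation_keep_rule": ablation_keep_rule,
                "scoring": scoring, "seed": seed})
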