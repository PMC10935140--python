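"""Grouped CV, imbalance-aware metrics, experiment drivers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wristfall import evaluation as ev, synthetic_data as sd
from wristfall import pipeline


# --- subject-grouped k-fold ------------------------------------------------

def _keys(n_subjects, rows_per_subject=3, dataset="D"):
    return [(dataset, s) for s in range(n_subjects)
            for _ in range(rows_per_subject)]


def test_loso_when_subjects_equal_k():
    fa = ev.subject_group_kfold(_keys(10), k=10, seed=0)
    sizes = [len(fa.subjects_in(f)) for f in range(10)]
    assert sizes == [1] * 10


def test_round_robin_even_split():
    fa = ev.subject_group_kfold(_keys(20), k=10, seed=1)
    sizes = [len(fa.subjects_in(f)) for f in range(10)]
    assert sizes == [2] * 10


@given(st.integers(5, 40), st.integers(2, 5), st.integers(0, 10))
def test_folds_partition_subjects(n_subjects, k, seed):
    keys = _keys(n_subjects)
    fa = ev.subject_group_kfold(keys, k=min(k, n_subjects), seed=seed)
    fold_sets = [fa.subjects_in(f) for f in range(fa.k)]
    union = set().union(*fold_sets)
    assert union == set(keys)
    for a, b in itertools.combinations(fold_sets, 2):
        assert not a & b


def test_kfold_rejects_too_few_subjects():
    with pytest.raises(ValueError, match="smaller k"):
        ev.subject_group_kfold(_keys(5), k=10, seed=0)


def test_kfold_retries_until_both_classes_per_fold():
    # only two of eight subjects carry positive rows; with k=2 a valid
    # assignment must split them across folds
    keys = _keys(8, rows_per_subject=4)
    y = np.zeros(len(keys), int)
    for i, (_, s) in enumerate(keys):
        if s in (0, 1):
            y[i] = i % 2  # subjects 0 and 1 have both classes
    found = ev.subject_group_kfold(keys, k=2, seed=0, y=y)
    for fold in range(2):
        subj = {s for _, s in found.subjects_in(fold)}
        assert subj & {0, 1}


# --- metrics ---------------------------------------------------------------

def test_confusion_metrics_worked_example():
    y_true = np.array([1] * 90 + [1] * 10 + [0] * 970 + [0] * 30)
    y_pred = np.array([1] * 90 + [0] * 10 + [0] * 970 + [1] * 30)
    m = ev.confusion_metrics(y_true, y_pred)
    assert m["recall"] == pytest.approx(0.90)
    assert m["specificity"] == pytest.approx(0.97)
    assert m["precision"] == pytest.approx(0.75)
    assert m["f1"] == pytest.approx(2 * 0.75 * 0.9 / 1.65)
    assert m["accuracy"] == pytest.approx(1060 / 1100)


def test_confusion_metrics_perfect_and_degenerate():
    m = ev.confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
    assert all(m[k] == 1.0 for k in m)
    with pytest.warns(UserWarning):
        m = ev.confusion_metrics([0, 1, 1, 0], [0, 0, 0, 0])
    assert m["recall"] == 0.0 and m["specificity"] == 1.0
    assert m["precision"] == 0.0
    with pytest.raises(ValueError):
        ev.confusion_metrics([0, 1], [0, 1, 1])


def test_roc_auc_examples():
    assert ev.roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3]) == \
        pytest.approx(0.75)
    assert ev.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert ev.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    with pytest.raises(ValueError):
        ev.roc_auc([1, 1], [0.1, 0.2])


def _pair_count_auc(y, s):
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _exhaustive_max_sesp(y, s):
    y, s = np.asarray(y), np.asarray(s)
    best = 0.0
    for thr in np.concatenate([s, [s.max() + 1]]):
        pred = (s >= thr).astype(int)
        se = (pred[y == 1] == 1).mean()
        sp = (pred[y == 0] == 0).mean()
        best = max(best, min(se, sp))
    return best


def test_auc_agrees_with_pair_counting():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = rng.integers(6, 40)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        assert ev.roc_auc(y, s) == pytest.approx(_pair_count_auc(y, s))


def test_max_sesp_examples_and_oracle():
    assert ev.max_sesp([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert ev.max_sesp([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.0
    assert ev.max_sesp([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3]) == \
        pytest.approx(0.5)
    rng = np.random.default_rng(1)
    for _ in range(30):
        n = rng.integers(6, 40)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 2)
        assert ev.max_sesp(y, s) == pytest.approx(
            _exhaustive_max_sesp(y, s))


@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1000)),
                min_size=4, max_size=50))
def test_auc_invariant_under_monotone_transform(pairs):
    y = np.array([p[0] for p in pairs])
    # coarse score grid keeps the transform injective in floating point
    s = np.array([p[1] for p in pairs]) / 1000.0
    if y.min() == y.max():
        return
    transformed = np.exp(3 * s) + 7
    assert ev.roc_auc(y, transformed) == pytest.approx(ev.roc_auc(y, s))
    assert ev.max_sesp(y, transformed) == pytest.approx(ev.max_sesp(y, s))


# --- experiment drivers ----------------------------------------------------

FAST = dict(run_selection=False)


def test_within_dataset_report_shape(small_corpus):
    cfg = ev.ExperimentConfig(k=4, seed=0, **FAST)
    rep = ev.run_within_dataset(small_corpus.features, "UpSim", "svm", cfg)
    assert len(rep.fold_metrics) == 4
    agg = rep.aggregates
    assert np.isfinite(agg["mean"]).all()
    # aggregate mean is the arithmetic mean of the fold values
    assert agg.loc["recall", "mean"] == pytest.approx(
        rep.fold_metrics["recall"].mean())


def test_within_dataset_auto_reduces_k(small_corpus):
    cfg = ev.ExperimentConfig(k=10, seed=0, **FAST)  # only 4 subjects
    rep = ev.run_within_dataset(small_corpus.features, "UmaSim", "svm", cfg)
    assert rep.descriptor["k"] == 4


def test_within_dataset_invariant_to_row_order(small_corpus):
    cfg = ev.ExperimentConfig(k=4, seed=3, **FAST)
    rep1 = ev.run_within_dataset(small_corpus.features, "WedaSim", "svm",
                                 cfg)
    shuffled = small_corpus.features.sample(frac=1.0, random_state=5)
    rep2 = ev.run_within_dataset(shuffled, "WedaSim", "svm", cfg)
    for m in ("recall", "specificity", "auc_roc"):
        assert sorted(rep1.fold_metrics[m]) == pytest.approx(
            sorted(rep2.fold_metrics[m]))


def test_combined_concatenates_all_sources(small_corpus):
    cfg = ev.ExperimentConfig(k=4, seed=0, **FAST)
    rep = ev.run_combined(small_corpus.features, "svm", cfg)
    per_source = small_corpus.features.groupby("dataset").size()
    assert rep.descriptor["n_windows"] == per_source.sum()
    assert rep.descriptor["train_datasets"] == sorted(per_source.index)


def test_combined_rejects_duplicate_windows(small_corpus):
    doubled = ev.pd.concat([small_corpus.features,
                            small_corpus.features.iloc[:5]])
    with pytest.raises(ValueError, match="duplicate"):
        ev.run_combined(doubled, "svm", ev.ExperimentConfig(k=4, **FAST))


def test_combined_fold_assignment_shared_across_tags(small_corpus):
    cfg = ev.ExperimentConfig(k=4, seed=2, **FAST)
    r1 = ev.run_combined(small_corpus.features, "svm", cfg,
                         normalization_mode="off")
    r2 = ev.run_combined(small_corpus.features, "svm", cfg,
                         normalization_mode="per_dataset")
    assert r1.fold_test_subjects == r2.fold_test_subjects
    assert r1.descriptor["normalization"] == "off"
    assert r2.descriptor["normalization"] == "per_dataset"


def test_cross_dataset_contract(small_corpus):
    cfg = ev.ExperimentConfig(seed=0, **FAST)
    names = sorted(small_corpus.features["dataset"].unique())
    for train in names:
        rest = [d for d in names if d != train]
        rep = ev.run_cross_dataset(small_corpus.features, train, rest,
                                   "svm", cfg)
        assert len(rep.fold_metrics) == 1
        test_subjects = set(rep.fold_test_subjects[0])
        assert all(ds != train for ds, _ in test_subjects)
    with pytest.raises(ValueError):
        ev.run_cross_dataset(small_corpus.features, names[0], names, "svm",
                             cfg)


def test_cross_dataset_recall_degrades_under_kinematic_shift(tmp_path):
    def _config(peak, orient):
        acts = (
            sd.ActivityProfile(activity_id=1, name="walk", is_fall=False,
                               oscillation_freq=1.8, oscillation_amp=0.25),
            sd.ActivityProfile(activity_id=2, name="sit", is_fall=False,
                               oscillation_freq=0.4, oscillation_amp=0.3),
            sd.ActivityProfile(activity_id=3, name="fall", is_fall=True,
                               impact_peak=peak,
                               post_impact_orientation_change=orient),
        )
        return acts

    def _two_sources(peak_b, orient_b, seed):
        src_a = sd.SourceConfig("A", 18.0, "g", "rad/s", 6,
                                _config(3.0, np.pi / 2))
        src_b = sd.SourceConfig("B", 18.0, "g", "rad/s", 6,
                                _config(peak_b, orient_b))
        return sd.GeneratorConfig(sources=(src_a, src_b), seed=seed)

    cfg = ev.ExperimentConfig(seed=0, k=6, **FAST)
    same = pipeline.build_corpus(tmp_path / "same",
                                 config=_two_sources(3.0, np.pi / 2, 2))
    shifted = pipeline.build_corpus(
        tmp_path / "shift", config=_two_sources(1.4, 0.15, 2))
    within = ev.run_within_dataset(same.features, "A", "svm", cfg)
    cross_same = ev.run_cross_dataset(same.features, "A", ["B"], "svm", cfg)
    cross_shift = ev.run_cross_dataset(shifted.features, "A", ["B"], "svm",
                                       cfg)
    within_recall = within.aggregates.loc["recall", "mean"]
    assert abs(cross_same.fold_metrics["recall"][0] - within_recall) <= 0.1
    assert cross_shift.fold_metrics["recall"][0] < \
        cross_same.fold_metrics["recall"][0]


def test_threshold_baseline_driver(small_corpus):
    out = ev.run_threshold_baseline(small_corpus.recordings, threshold=2.5)
    assert out["n_windows"] == len(small_corpus.features)
    assert out["min_sesp"] == min(out["recall"], out["specificity"])
    assert 0 <= out["max_sesp"] <= 1


def test_report_json_roundtrip(tmp_path, small_corpus):
    cfg = ev.ExperimentConfig(k=4, seed=0, **FAST)
    rep = ev.run_within_dataset(small_corpus.features, "UpSim", "ann", cfg)
    rep.to_json(tmp_path / "report.json")
    assert (tmp_path / "report.json").stat().st_size > 100
    assert "recall" in rep.summary()
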