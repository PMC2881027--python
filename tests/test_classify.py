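"""Randomized imbalance-aware forest protocol."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from orgproteome.classify import (
    INPUT_TYPE_GRID,
    ModelSelection,
    PooledVoteForestClassifier,
    ProtocolConfig,
    RandomizationRun,
    compare_input_types,
    run_protocol,
    select_best_run,
    split_P,
)
from orgproteome.features import CompositionVectorizer
from orgproteome.simulate import GeneratorConfig, generate_training_sets, transition_matrices

FAST = ProtocolConfig(n_trees=60, n_randomizations=6, base_seed=0)


def _make_run(idx, accuracy, recall):
    return RandomizationRun(
        run_index=idx, p_split={}, oob_votes=np.zeros((1, 3)),
        pooled_confusion=np.zeros((2, 2), dtype=int), oob_error=0.5,
        accuracy=accuracy, recall_A=recall,
    )


class TestSplitP:
    def test_sizes_and_determinism(self):
        p = list(range(59))
        p1, p2 = split_P(p, seed=4)
        assert sorted([len(p1), len(p2)]) == [29, 30]
        assert split_P(p, seed=4) == (p1, p2)
        assert split_P(p, seed=5) != (p1, p2)

    def test_partition_property(self):
        for n in (2, 3, 10, 59):
            p = list(range(n))
            p1, p2 = split_P(p, seed=0)
            assert sorted(p1 + p2) == p
            assert abs(len(p1) - len(p2)) <= 1

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_P([1], seed=0)


def test_selection_prefers_recall_on_accuracy_tie():
    runs = [_make_run(0, 0.9, 0.5), _make_run(1, 0.9, 0.8), _make_run(2, 0.85, 1.0)]
    assert select_best_run(runs).run_index == 1
    # strict accuracy dominance still wins
    runs.append(_make_run(3, 0.95, 0.0))
    assert select_best_run(runs).run_index == 3
    # full tie -> earliest run
    assert select_best_run([_make_run(0, 0.9, 0.5), _make_run(1, 0.9, 0.5)]).run_index == 0


@pytest.fixture(scope="module")
def fitted(small_training_sets):
    A, P = small_training_sets
    runs, selection, clf = run_protocol(A, P, FAST)
    return A, P, runs, selection, clf


class TestProtocol:
    def test_confusion_conservation(self, fitted):
        A, P, runs, _, _ = fitted
        for run in runs:
            assert run.pooled_confusion.sum() == len(A) + len(P)
            assert 0 <= run.accuracy <= 1 and 0 <= run.recall_A <= 1
            assert 0 <= run.oob_error <= 1

    def test_three_class_error_dominates_pooled_error(self, fitted):
        _, _, runs, _, _ = fitted
        for run in runs:
            assert run.oob_error >= 1 - run.accuracy

    def test_split_sizes_balanced(self, fitted):
        _, P, runs, _, _ = fitted
        for run in runs:
            sizes = list(np.unique(list(run.p_split.values()), return_counts=True)[1])
            assert abs(sizes[0] - sizes[1]) <= 1 and sum(sizes) == len(P)

    def test_reproducible_given_base_seed(self, fitted, small_training_sets):
        A, P = small_training_sets
        _, _, runs, selection, _ = fitted
        runs2, selection2, _ = run_protocol(A, P, FAST)
        assert [r.accuracy for r in runs] == [r.accuracy for r in runs2]
        assert selection.best_run_index == selection2.best_run_index

    def test_selection_statistics(self, fitted):
        _, _, runs, selection, _ = fitted
        errors = [r.oob_error for r in runs]
        assert selection.oob_error_mean == pytest.approx(np.mean(errors))
        assert selection.oob_error_sd == pytest.approx(np.std(errors, ddof=1))
        best = runs[selection.best_run_index]
        assert all(best.accuracy >= r.accuracy for r in runs)

    def test_predict_api(self, fitted, small_training_sets):
        A, P = small_training_sets
        _, _, _, _, clf = fitted
        vec = CompositionVectorizer(region="full", order=2).fit([])
        X = vec.transform(A[:3] + P[:3])
        proba = clf.predict_proba(X)
        assert proba.shape == (6, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        preds = clf.predict(X)
        assert set(preds) <= {"A", "P"}


def test_requires_two_classes():
    clf = PooledVoteForestClassifier(n_trees=10, n_randomizations=2)
    X = np.random.default_rng(0).random((9, 4))
    with pytest.raises(ValueError, match="two classes"):
        clf.fit(X, np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3))


def test_sklearn_estimator_contract():
    clf = PooledVoteForestClassifier(n_trees=5, n_randomizations=2, base_seed=3)
    params = clf.get_params()
    assert params["n_trees"] == 5
    clf2 = clone(clf)
    assert clf2.get_params() == params


def test_compare_input_types_structure(small_training_sets):
    A, P = small_training_sets
    table = compare_input_types(A[:10], P[:14], ProtocolConfig(n_trees=40, n_randomizations=3))
    assert len(table) == len(INPUT_TYPE_GRID) == 6
    assert set(zip(table["region"], table["order"])) == set(INPUT_TYPE_GRID)


def test_shared_signal_peptides_carry_no_class_signal(small_training_sets):
    """Signal peptides come from one shared model, so sp-region classifiers
    hover near the majority-class rate while mature-region ones separate."""
    cfg = GeneratorConfig(seed=21, n_A=20, n_P=40, divergence=3.0)
    A, P = generate_training_sets(cfg)
    table = compare_input_types(A, P, ProtocolConfig(n_trees=80, n_randomizations=4))
    by_type = table.set_index(["region", "order"])["best_accuracy"]
    majority = 40 / 60
    assert by_type[("mature", 2)] > 0.95
    assert by_type[("full", 2)] > 0.95
    assert by_type[("sp", 2)] < majority + 0.15
    assert by_type[("sp", 1)] < majority + 0.15


def test_importances_track_generative_contrast():
    """Top RF dipeptide importances correlate with the true expected
    dipeptide-frequency contrast between the two chain models."""
    cfg = GeneratorConfig(seed=13, n_A=25, n_P=50, divergence=2.0)
    A, P = generate_training_sets(cfg)
    proto = ProtocolConfig(n_trees=150, n_randomizations=3, base_seed=1, region="mature")
    _, _, clf = run_protocol(A, P, proto)
    models = transition_matrices(cfg)
    diff = np.abs(
        models["A_init"][:, None] * models["A"] - models["P_init"][:, None] * models["P"]
    ).ravel()
    imp = clf.best_forest_.feature_importances_
    rho = stats.spearmanr(imp, diff).statistic
    assert rho > 0.2
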