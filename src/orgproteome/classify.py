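"""Class-imbalance-aware randomized random-forest protocol.

The two soluble training classes are unbalanced (organellar set A is roughly
half the size of cell-envelope set P). To avoid a majority-class bias, each
training round splits P uniformly at random into halves P1 and P2 of
near-equal size to A, trains a three-class forest (A, P1, P2), and evaluates
it on out-of-bag (OOB) votes only: for every protein the OOB vote fractions
for P1 and P2 are pooled into one P vote, the protein is classified by
arg-max over {A, pooled P} (ties go to P, conservative against organellar
calls), and pooled two-class accuracy, set-A recall and the three-class OOB
error are recorded. The round is repeated many times with fresh splits; the
best round is the one maximising accuracy, ties broken by set-A recall.

:class:`PooledVoteForestClassifier` implements the protocol as a
scikit-learn estimator so it composes with pipelines and model selection;
:func:`run_protocol` and :func:`compare_input_types` are thin wrappers that
start from protein records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .features import CompositionVectorizer
from .records import ProteinRecord


@dataclass
class ProtocolConfig:
    """Protocol settings: forest size, number of P-set randomizations, the
    base seed, and which feature space to use (region x order)."""

    n_trees: int = 1000
    n_randomizations: int = 500
    base_seed: int = 0
    region: str = "full"
    order: int = 2
    exclusion_mode: str = "none"

    def validate(self) -> None:
        if self.n_trees < 1 or self.n_randomizations < 1:
            raise ValueError("n_trees and n_randomizations must be >= 1")


@dataclass
class RandomizationRun:
    """Metrics of one P-randomization round, evaluated on pooled OOB votes."""

    run_index: int
    p_split: Dict[int, str]           # majority-sample row index -> "P1"/"P2"
    oob_votes: np.ndarray             # (n_samples, 3) fractions over (A, P1, P2)
    pooled_confusion: np.ndarray      # 2x2 counts, rows true (A, P), cols predicted
    oob_error: float                  # three-class OOB misclassification rate
    accuracy: float                   # pooled two-class accuracy
    recall_A: float                   # pooled recall of the minority class


@dataclass
class ModelSelection:
    """Best run (max accuracy, ties by minority recall) plus run-ensemble stats."""

    best_run_index: int
    accuracy: float
    recall_A: float
    oob_error_mean: float
    oob_error_sd: float
    top_features: List[Tuple[str, float]]


def split_P(P: Sequence, seed: int) -> Tuple[list, list]:
    """Uniform random partition of the majority set into near-equal halves.

    Sizes differ by at most one; deterministic for a given seed.
    """
    if len(P) < 2:
        raise ValueError("need at least 2 majority-class members to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(P))
    n1 = (len(P) + 1) // 2
    P = list(P)
    return [P[i] for i in perm[:n1]], [P[i] for i in perm[n1:]]


def select_best_run(runs: Sequence[RandomizationRun]) -> RandomizationRun:
    """Max accuracy; ties broken by higher minority-class recall, then by
    the earliest run index (stable)."""
    return max(runs, key=lambda r: (r.accuracy, r.recall_A, -r.run_index))


class PooledVoteForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with majority-class splitting and pooled OOB votes.

    Fit on a two-class problem where the majority class is randomly split in
    two for each of ``n_randomizations`` rounds; each round trains a
    three-class forest of ``n_trees`` trees with out-of-bag scoring and
    evaluates by pooled votes. ``runs_`` holds every round,
    ``selection_`` the chosen model, and ``best_forest_`` the refitted
    forest of the best round used by :meth:`predict`.

    Parameters
    ----------
    n_trees : int
        Trees per forest.
    n_randomizations : int
        Number of majority-set randomization rounds.
    base_seed : int
        Round ``i`` uses seed ``base_seed + i`` for both the split and the
        forest, so any single round is independently reproducible.
    minority_label : str or None
        Label of the class kept intact; inferred as the rarer class when None.
    n_top_features : int
        Number of ranked feature importances retained from the best round.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        n_randomizations: int = 500,
        base_seed: int = 0,
        minority_label: Optional[str] = None,
        n_top_features: int = 25,
    ):
        self.n_trees = n_trees
        self.n_randomizations = n_randomizations
        self.base_seed = base_seed
        self.minority_label = minority_label
        self.n_top_features = n_top_features

    # -- internal ----------------------------------------------------------

    def _forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )

    def _one_run(
        self, run_index: int, X: np.ndarray, y: np.ndarray,
        minority: str, majority: str,
    ) -> RandomizationRun:
        seed = self.base_seed + run_index
        maj_idx = np.flatnonzero(y == majority)
        half1, half2 = split_P(list(maj_idx), seed)
        y3 = y.astype(object).copy()
        y3[np.array(half1, dtype=int)] = f"{majority}1"
        y3[np.array(half2, dtype=int)] = f"{majority}2"
        forest = self._forest(seed)
        with np.errstate(invalid="ignore"):
            forest.fit(X, y3)
        classes = list(forest.classes_)
        votes = np.asarray(forest.oob_decision_function_, dtype=float)
        votes = np.nan_to_num(votes, nan=0.0)  # never-OOB rows -> tie -> majority
        order = [classes.index(minority), classes.index(f"{majority}1"),
                 classes.index(f"{majority}2")]
        votes = votes[:, order]  # columns (A, P1, P2)

        pooled_minority = votes[:, 0]
        pooled_majority = votes[:, 1] + votes[:, 2]
        pred2 = np.where(pooled_minority > pooled_majority, minority, majority)

        is_min = y == minority
        tp = int(np.sum((pred2 == minority) & is_min))
        fn = int(np.sum((pred2 == majority) & is_min))
        fp = int(np.sum((pred2 == minority) & ~is_min))
        tn = int(np.sum((pred2 == majority) & ~is_min))
        confusion = np.array([[tp, fn], [fp, tn]])
        accuracy = (tp + tn) / len(y)
        recall = tp / max(is_min.sum(), 1)

        pred3 = np.array(["", "", ""], dtype=object)
        labels3 = np.array([minority, f"{majority}1", f"{majority}2"], dtype=object)
        pred3 = labels3[np.argmax(votes, axis=1)]
        oob_error = float(np.mean(pred3 != y3))

        p_split = {int(i): f"{majority}1" for i in half1}
        p_split.update({int(i): f"{majority}2" for i in half2})
        return RandomizationRun(
            run_index=run_index, p_split=p_split, oob_votes=votes,
            pooled_confusion=confusion, oob_error=oob_error,
            accuracy=float(accuracy), recall_A=float(recall),
        )

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        if self.n_trees < 1 or self.n_randomizations < 1:
            raise ValueError("n_trees and n_randomizations must be >= 1")
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) != 2:
            raise ValueError(f"exactly two classes required, got {list(labels)}")
        if self.minority_label is not None:
            if self.minority_label not in labels:
                raise ValueError(f"minority_label {self.minority_label!r} not in y")
            minority = self.minority_label
        else:
            minority = labels[np.argmin(counts)]
        majority = [l for l in labels if l != minority][0]
        self.classes_ = np.array(sorted(labels))
        self.minority_label_ = minority
        self.majority_label_ = majority
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = (
            np.asarray(feature_names, dtype=object) if feature_names is not None else None
        )

        self.runs_ = [
            self._one_run(i, X, y, minority, majority)
            for i in range(self.n_randomizations)
        ]
        best = select_best_run(self.runs_)

        # refit the winning round's forest for downstream prediction
        seed = self.base_seed + best.run_index
        maj_idx = np.flatnonzero(y == majority)
        half1, half2 = split_P(list(maj_idx), seed)
        y3 = y.astype(object).copy()
        y3[np.array(half1, dtype=int)] = f"{majority}1"
        y3[np.array(half2, dtype=int)] = f"{majority}2"
        self.best_forest_ = self._forest(seed)
        with np.errstate(invalid="ignore"):
            self.best_forest_.fit(X, y3)

        importances = self.best_forest_.feature_importances_
        names = (
            list(self.feature_names_in_)
            if self.feature_names_in_ is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        ranked = sorted(zip(names, importances), key=lambda t: -t[1])
        errors = np.array([r.oob_error for r in self.runs_])
        self.selection_ = ModelSelection(
            best_run_index=best.run_index,
            accuracy=best.accuracy,
            recall_A=best.recall_A,
            oob_error_mean=float(errors.mean()),
            oob_error_sd=float(errors.std(ddof=1)) if len(errors) > 1 else 0.0,
            top_features=[(n, float(v)) for n, v in ranked[: self.n_top_features]],
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Pooled vote fractions, columns ordered as ``classes_``."""
        check_is_fitted(self, "best_forest_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        proba3 = self.best_forest_.predict_proba(np.asarray(X, dtype=float))
        classes3 = list(self.best_forest_.classes_)
        v_min = proba3[:, classes3.index(self.minority_label_)]
        v_maj = (
            proba3[:, classes3.index(f"{self.majority_label_}1")]
            + proba3[:, classes3.index(f"{self.majority_label_}2")]
        )
        out = np.empty((len(proba3), 2))
        for j, label in enumerate(self.classes_):
            out[:, j] = v_min if label == self.minority_label_ else v_maj
        return out

    def predict(self, X) -> np.ndarray:
        """Arg-max of pooled votes; ties go to the majority class."""
        proba = self.predict_proba(X)
        j_min = list(self.classes_).index(self.minority_label_)
        j_maj = 1 - j_min
        pred = np.where(proba[:, j_min] > proba[:, j_maj],
                        self.minority_label_, self.majority_label_)
        return pred.astype(object)


# ---------------------------------------------------------------------------
# record-level wrappers


def run_protocol(
    A: Sequence[ProteinRecord],
    P: Sequence[ProteinRecord],
    cfg: ProtocolConfig,
) -> Tuple[List[RandomizationRun], ModelSelection, PooledVoteForestClassifier]:
    """Featurize two record sets per *cfg* and run the full protocol."""
    cfg.validate()
    if not A or not P:
        raise ValueError("both training sets must be nonempty")
    vec = CompositionVectorizer(region=cfg.region, order=cfg.order,
                                exclusion_mode=cfg.exclusion_mode).fit([])
    X = vec.transform(list(A) + list(P))
    y = np.array(["A"] * len(A) + ["P"] * len(P), dtype=object)
    clf = PooledVoteForestClassifier(
        n_trees=cfg.n_trees, n_randomizations=cfg.n_randomizations,
        base_seed=cfg.base_seed, minority_label="A",
    )
    clf.fit(X, y, feature_names=vec.feature_names_)
    return clf.runs_, clf.selection_, clf


INPUT_TYPE_GRID: Tuple[Tuple[str, int], ...] = (
    ("full", 1), ("full", 2), ("sp", 1), ("sp", 2), ("mature", 1), ("mature", 2),
)


def compare_input_types(
    A: Sequence[ProteinRecord],
    P: Sequence[ProteinRecord],
    cfg: ProtocolConfig,
) -> pd.DataFrame:
    """Run the protocol for all six input types (region x feature order).

    Returns one row per input type with the best round's accuracy and
    minority-class recall plus the mean OOB error over rounds.
    """
    rows = []
    for region, order in INPUT_TYPE_GRID:
        sub = ProtocolConfig(
            n_trees=cfg.n_trees, n_randomizations=cfg.n_randomizations,
            base_seed=cfg.base_seed, region=region, order=order,
            exclusion_mode=cfg.exclusion_mode,
        )
        _, selection, _ = run_protocol(A, P, sub)
        rows.append({
            "region": region, "order": order,
            "best_accuracy": selection.accuracy,
            "best_recall_A": selection.recall_A,
            "oob_error_mean": selection.oob_error_mean,
        })
    return pd.DataFrame(rows)
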