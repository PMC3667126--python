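"""Balanced-resampling classification of toxicity with feature ablation.

Toxic proteins are the minority class, so each repetition of the protocol
draws all minority-class proteins plus an equal-size uniform sample of the
majority class, fits a random forest on the balanced set, and scores every
balanced-set protein by its out-of-bag positive-vote fraction — the
internal error estimate of bagged ensembles, which needs no explicit
held-out split.  The per-repetition ROC-AUC is averaged over repetitions
(10 by default).  Running the protocol on the sequence-feature subset, the
functional-flag subset and their union measures how much independent
predictive signal each group carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

#: the canonical feature subsets of the ablation comparison
FEATURE_SUBSETS: dict[str, list[str]] = {
    "SEQUENCE": ["positive_count", "pI", "length"],
    "FUNCTION": ["is_tf", "is_regulatory", "is_catalytic"],
    "COMBINED": ["positive_count", "pI", "length", "is_tf", "is_regulatory", "is_catalytic"],
}

#: offset separating the learner seed stream from the subsampling stream
LEARNER_SEED_OFFSET = 10_000


@dataclass
class ClassificationReport:
    """Per-repetition and mean ROC-AUC for a named feature subset."""

    feature_subset_name: str
    feature_names: list[str]
    n_repetitions: int
    per_rep_auc: list[float]
    mean_auc: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.per_rep_auc) != self.n_repetitions:
            raise ValueError("per_rep_auc length must equal n_repetitions")
        if abs(self.mean_auc - float(np.mean(self.per_rep_auc))) > 1e-12:
            raise ValueError("mean_auc must be the mean of per_rep_auc")


def balanced_subsample(
    toxic_ids: Sequence[str], nontoxic_ids: Sequence[str], seed: int
) -> list[str]:
    """All minority-class ids plus an equal-size uniform sample (without
    replacement) of the majority class; deterministic given the seed."""
    toxic = list(toxic_ids)
    nontoxic = list(nontoxic_ids)
    if not toxic or not nontoxic:
        raise ValueError("both classes must be non-empty")
    minority, majority = (toxic, nontoxic) if len(toxic) <= len(nontoxic) else (nontoxic, toxic)
    rng = np.random.default_rng(seed)
    sampled = rng.choice(len(majority), size=len(minority), replace=False)
    return minority + [majority[i] for i in sorted(sampled)]


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability a random positive outscores a random negative, ties
    counting 1/2 (the trapezoidal area under the ROC curve)."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(y, s))


def _default_learner(seed: int, n_estimators: int, oob: bool) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


class BalancedForestProtocol(ClassifierMixin, BaseEstimator):
    """Repeated balanced-subsampling random-forest protocol.

    ``fit`` runs ``n_repetitions`` rounds.  Round ``r`` draws a balanced
    sample with seed ``random_state + r`` and fits a forest seeded
    ``random_state + 10000 + r``, so different feature subsets evaluated at
    the same ``random_state`` see identical balanced sets.  ROC scores come
    either from out-of-bag positive-vote fractions on the balanced set
    (``holdout="oob"``, the default) or from a 70/30 split
    (``holdout="split"``).

    Parameters
    ----------
    feature_names : list of str or None
        Columns used; None means all columns of X.
    n_repetitions : int
        Balanced-resampling rounds (default 10).
    n_estimators : int
        Trees per forest (default 500).
    holdout : {"oob", "split"}
        ROC scoring route.
    random_state : int
        Master seed of the two derived streams.
    learner_factory : callable ``(seed) -> classifier`` or None
        Plug in a different ensemble; it must expose ``oob_decision_function_``
        after fit when ``holdout="oob"``.

    Attributes
    ----------
    report_ : ClassificationReport
        Per-repetition and mean ROC-AUC.
    estimators_ : list of fitted classifiers, one per repetition.
    classes_ : ndarray of the two label values.
    feature_names_in_ : ndarray of the columns used.
    """

    def __init__(
        self,
        feature_names: list[str] | None = None,
        n_repetitions: int = 10,
        n_estimators: int = 500,
        holdout: str = "oob",
        random_state: int = 0,
        learner_factory: Callable[[int], BaseEstimator] | None = None,
        subset_name: str = "custom",
    ):
        self.feature_names = feature_names
        self.n_repetitions = n_repetitions
        self.n_estimators = n_estimators
        self.holdout = holdout
        self.random_state = random_state
        self.learner_factory = learner_factory
        self.subset_name = subset_name

    def _make_learner(self, seed: int) -> BaseEstimator:
        if self.learner_factory is not None:
            return self.learner_factory(seed)
        return _default_learner(seed, self.n_estimators, oob=self.holdout == "oob")

    def fit(self, X: pd.DataFrame, y: Sequence[bool]):
        if self.holdout not in ("oob", "split"):
            raise ValueError(f"holdout must be 'oob' or 'split', got {self.holdout!r}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if len(X) != len(y):
            raise ValueError("X and y must align")
        cols = list(self.feature_names) if self.feature_names else list(X.columns)
        if not cols:
            raise ValueError("feature subset must be non-empty")
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"features not in table: {missing}")
        if y.all() or not y.any():
            raise ValueError("cohort must contain both classes")
        Xs = X[cols].astype(float)
        for c in cols:
            if Xs[c].nunique() <= 1:
                warnings.warn(f"feature {c!r} is constant; proceeding", stacklevel=2)

        index = np.asarray(X.index)
        toxic_ids = list(index[y])
        nontoxic_ids = list(index[~y])
        pos = pd.Series(y, index=index)

        aucs: list[float] = []
        self.estimators_ = []
        for r in range(self.n_repetitions):
            chosen = balanced_subsample(toxic_ids, nontoxic_ids, self.random_state + r)
            Xb = Xs.loc[chosen].to_numpy()
            yb = pos.loc[chosen].to_numpy()
            learner_seed = self.random_state + LEARNER_SEED_OFFSET + r
            clf = self._make_learner(learner_seed)
            if self.holdout == "oob":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # rare all-in-bag samples
                    clf.fit(Xb, yb)
                votes = clf.oob_decision_function_[:, list(clf.classes_).index(True)]
                mask = ~np.isnan(votes)
                aucs.append(roc_auc(votes[mask], yb[mask]))
            else:
                Xtr, Xte, ytr, yte = train_test_split(
                    Xb, yb, test_size=0.3, random_state=learner_seed, stratify=yb
                )
                clf.fit(Xtr, ytr)
                scores = clf.predict_proba(Xte)[:, list(clf.classes_).index(True)]
                aucs.append(roc_auc(scores, yte))
            self.estimators_.append(clf)

        self.classes_ = np.array([False, True])
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = len(cols)
        self.report_ = ClassificationReport(
            feature_subset_name=self.subset_name,
            feature_names=cols,
            n_repetitions=self.n_repetitions,
            per_rep_auc=[float(a) for a in aucs],
            mean_auc=float(np.mean(aucs)),
            seed=self.random_state,
        )
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Mean vote fraction across the repetition forests."""
        check_is_fitted(self, "estimators_")
        Xs = pd.DataFrame(X)[list(self.feature_names_in_)].astype(float).to_numpy()
        probs = np.mean(
            [
                est.predict_proba(Xs)[:, list(est.classes_).index(True)]
                for est in self.estimators_
            ],
            axis=0,
        )
        return np.column_stack([1 - probs, probs])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= 0.5


def run_protocol(
    features: pd.DataFrame,
    toxic_flags: Sequence[bool],
    feature_subset: Sequence[str] | str,
    n_repetitions: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    holdout: str = "oob",
) -> ClassificationReport:
    """Run the balanced-resampling protocol on one feature subset.

    ``feature_subset`` may be a named subset ("SEQUENCE", "FUNCTION",
    "COMBINED") or an explicit list of feature columns.
    """
    if isinstance(feature_subset, str):
        name = feature_subset
        cols = FEATURE_SUBSETS[feature_subset]
    else:
        cols = list(feature_subset)
        name = "custom"
    est = BalancedForestProtocol(
        feature_names=cols,
        n_repetitions=n_repetitions,
        n_estimators=n_estimators,
        holdout=holdout,
        random_state=seed,
        subset_name=name,
    )
    est.fit(features, toxic_flags)
    return est.report_


def ablation_compare(
    features: pd.DataFrame,
    toxic_flags: Sequence[bool],
    seed: int = 0,
    n_repetitions: int = 10,
    n_estimators: int = 500,
    holdout: str = "oob",
    extra_subsets: dict[str, list[str]] | None = None,
) -> list[ClassificationReport]:
    """Run the protocol on SEQUENCE, FUNCTION and COMBINED (plus any extra
    named subsets) under the same seed schedule, so every subset sees the
    same balanced samples."""
    reports = [
        run_protocol(
            features, toxic_flags, name,
            n_repetitions=n_repetitions, seed=seed,
            n_estimators=n_estimators, holdout=holdout,
        )
        for name in ("SEQUENCE", "FUNCTION", "COMBINED")
    ]
    for name, cols in (extra_subsets or {}).items():
        rep = run_protocol(
            features, toxic_flags, cols,
            n_repetitions=n_repetitions, seed=seed,
            n_estimators=n_estimators, holdout=holdout,
        )
        rep.feature_subset_name = name
        reports.append(rep)
    return reports
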