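"""Two-way ensemble classification between recorded units and model classes.

The classifier is a Monte-Carlo cross-validated ensemble: ``n_boot``
independent random 75/25 train/validation splits, the minority classes
oversampled with replacement to a 1:1 ratio on the training split only,
one member fitted per split — a linear-margin SVM (C = 1) for two classes
or a gini random forest for more — and the held-out confusion matrices
pooled across splits.  Prediction is the majority vote over members.

``cross_map`` realises the bidirectional mapping protocol: an ensemble
trained on one labelled domain (e.g. simulated cell-class waveform
features) is applied to the other (e.g. in vivo clusters), and the
class-by-prediction contingency table is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .errors import InsufficientDataError, ParameterError, SchemaError

__all__ = [
    "MonteCarloEnsembleClassifier",
    "MappingTable",
    "train_ensemble",
    "predict_majority",
    "cross_map",
]

logger = logging.getLogger(__name__)


class MonteCarloEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of classifiers over Monte-Carlo train/validation splits.

    Parameters
    ----------
    n_boot : int
        Number of independent splits/members (100 in the reference
        protocol).
    train_fraction : float
        Fraction of samples in each training split.
    balance : bool
        Oversample minority classes with replacement to 1:1 on the
        training split (validation sets are never resampled).
    family : {"auto", "svm", "forest"}
        "auto" picks a linear SVM (C = 1) for two classes and a gini
        random forest otherwise.
    n_trees : int
        Forest size when the forest family is used.

    Fitted attributes
    -----------------
    members_ : list of (scaler_mean, scaler_scale, estimator)
    validation_confusion_ : DataFrame, pooled over all held-out partitions
    validation_accuracy_ : float, pooled over held-out predictions
    per_member_accuracy_ : ndarray, accuracy of each member on its split
    accuracy_se_ : float, SE of the per-member accuracies
    """

    def __init__(
        self,
        n_boot: int = 100,
        train_fraction: float = 0.75,
        balance: bool = True,
        family: str = "auto",
        C: float = 1.0,
        n_trees: int = 500,
        feature_names: list | None = None,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.train_fraction = train_fraction
        self.balance = balance
        self.family = family
        self.C = C
        self.n_trees = n_trees
        self.feature_names = feature_names
        self.random_state = random_state

    def _make_member(self, n_classes: int, seed: int):
        family = self.family
        if family == "auto":
            family = "svm" if n_classes == 2 else "forest"
        if family == "svm":
            return SVC(kernel="linear", C=self.C, random_state=seed)
        if family == "forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, criterion="gini", random_state=seed
            )
        raise ParameterError(f"unknown classifier family {family!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ParameterError("X must be (n_samples, n_features) matching y")
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size < 2:
            raise InsufficientDataError("need at least 2 classes")
        if counts.min() < 4:
            raise InsufficientDataError(
                f"class {self.classes_[counts.argmin()]!r} has fewer than 4 members"
            )
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        members = []
        confusion = np.zeros((self.classes_.size, self.classes_.size), dtype=int)
        per_acc = np.empty(self.n_boot)
        train_counts = []
        n_pooled_correct = 0
        n_pooled = 0
        for b in range(self.n_boot):
            split_seed = int(rng.integers(0, 2**31 - 1))
            Xtr, Xva, ytr, yva = train_test_split(
                X, y,
                train_size=self.train_fraction,
                random_state=split_seed,
                stratify=y,
            )
            # standardization statistics come from the training split only
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            if self.balance:
                Xtr, ytr = _oversample(Xtr, ytr, rng)
            cls, cnt = np.unique(ytr, return_counts=True)
            train_counts.append(dict(zip(cls.tolist(), cnt.tolist())))
            est = self._make_member(self.classes_.size, split_seed)
            est.fit((Xtr - mu) / sd, ytr)
            pred = est.predict((Xva - mu) / sd)
            confusion += confusion_matrix(yva, pred, labels=self.classes_)
            per_acc[b] = np.mean(pred == yva)
            n_pooled_correct += int(np.sum(pred == yva))
            n_pooled += yva.size
            members.append((mu, sd, est))

        self.members_ = members
        self.train_class_counts_ = train_counts
        self.validation_confusion_ = pd.DataFrame(
            confusion, index=self.classes_, columns=self.classes_
        )
        self.validation_accuracy_ = n_pooled_correct / n_pooled
        self.per_member_accuracy_ = per_acc
        self.accuracy_se_ = float(per_acc.std(ddof=1) / np.sqrt(self.n_boot))
        self.train_bounds_ = (
            np.percentile(X, 1, axis=0),
            np.percentile(X, 99, axis=0),
        )
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        return X

    def member_votes(self, X) -> np.ndarray:
        """(n_members, n_samples) label matrix of individual member predictions."""
        X = self._check_X(X)
        return np.stack([est.predict((X - mu) / sd) for mu, sd, est in self.members_])

    def predict_with_votes(self, X):
        """Majority-vote labels plus vote fraction and tie flags.

        Ties are broken toward the lexicographically smallest label and
        flagged.
        """
        votes = self.member_votes(X)
        n_members = votes.shape[0]
        labels = np.empty(votes.shape[1], dtype=self.classes_.dtype)
        frac = np.empty(votes.shape[1])
        ties = np.zeros(votes.shape[1], dtype=bool)
        for i in range(votes.shape[1]):
            vals, cnt = np.unique(votes[:, i], return_counts=True)
            top = cnt.max()
            winners = np.sort(vals[cnt == top])
            labels[i] = winners[0]
            frac[i] = top / n_members
            ties[i] = winners.size > 1
        return labels, frac, ties

    def predict(self, X):
        return self.predict_with_votes(X)[0]


def _oversample(X, y, rng) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes with replacement to a 1:1 ratio."""
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    parts_X, parts_y = [], []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt < target:
            extra = rng.choice(idx, size=target - cnt, replace=True)
            idx = np.concatenate([idx, extra])
        parts_X.append(X[idx])
        parts_y.append(y[idx])
    return np.vstack(parts_X), np.concatenate(parts_y)


@dataclass
class MappingTable:
    """Source-label by predicted-label contingency of a cross-domain mapping."""

    counts: pd.DataFrame  # rows: source labels, columns: predicted labels
    proportions: pd.DataFrame  # rows normalised to 1
    majority_map: dict  # source label -> most frequent predicted label
    vote_fraction: np.ndarray  # per test sample
    extrapolation_warning: bool = False

    @property
    def accuracy_on_diagonal(self) -> float:
        """Fraction on the diagonal for tables with matching label sets."""
        common = [c for c in self.counts.index if c in self.counts.columns]
        diag = sum(self.counts.loc[c, c] for c in common)
        return diag / self.counts.to_numpy().sum()


def train_ensemble(
    X, y, n_boot: int = 100, train_fraction: float = 0.75,
    balance: bool = True, seed: int | None = None, **kw
) -> MonteCarloEnsembleClassifier:
    return MonteCarloEnsembleClassifier(
        n_boot=n_boot, train_fraction=train_fraction, balance=balance,
        random_state=seed, **kw
    ).fit(X, y)


def predict_majority(ens: MonteCarloEnsembleClassifier, X):
    """Per-sample mode over ensemble members (ties lexicographic + flagged)."""
    return ens.predict_with_votes(X)


def cross_map(
    train_domain: tuple[np.ndarray, np.ndarray],
    test_domain: tuple[np.ndarray, np.ndarray],
    n_boot: int = 100,
    seed: int | None = None,
    **kw,
) -> MappingTable:
    """Train on one labelled domain, apply to the other, tabulate the mapping."""
    Xtr, ytr = train_domain
    Xte, yte = test_domain
    ens = train_ensemble(Xtr, ytr, n_boot=n_boot, seed=seed, **kw)
    pred, frac, _ = ens.predict_with_votes(Xte)

    lo, hi = ens.train_bounds_
    Xte_arr = np.asarray(Xte, dtype=float)
    outside = np.mean(np.any((Xte_arr < lo) | (Xte_arr > hi), axis=1))
    extrapolation = bool(outside > 0.5)
    if extrapolation:
        logger.warning(
            "cross_map: %.0f%% of test samples fall outside the 1-99 percentile "
            "support of the training domain", 100 * outside,
        )

    src_labels = np.unique(yte)
    counts = pd.DataFrame(
        0, index=src_labels, columns=ens.classes_, dtype=int
    )
    for s, p in zip(yte, pred):
        counts.loc[s, p] += 1
    proportions = counts.div(counts.sum(axis=1), axis=0)
    majority = {s: counts.loc[s].idxmax() for s in src_labels}
    return MappingTable(
        counts=counts,
        proportions=proportions,
        majority_map=majority,
        vote_fraction=frac,
        extrapolation_warning=extrapolation,
    )
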