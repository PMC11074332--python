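"""Undersampling soft-voting ensemble of feed-forward grade classifiers.

`EnsembleDDIClassifier` is the package's central estimator.  fit() splits
the majority grade across k member subsets (minority grades are copied
into every subset), computes inverse-frequency class weights per subset,
and trains one member network per subset with a seed derived from the
master seed.  predict_proba() soft-votes: the elementwise mean of the
members' 4-way probability vectors; predict() takes the argmax, breaking
exact ties toward the more severe grade (clinically conservative,
configurable).

With ``n_members=1, undersample=False, class_weight=None`` the estimator
degenerates to the plain single softmax classifier used as the
non-ensemble baseline.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .grades import GRADE_ORDER, GradeLabel, N_GRADES
from .imbalance import partition_indices, weights_from_labels
from .network import MLPSoftmax, NetworkSpec, resolve_spec

logger = logging.getLogger(__name__)


def soft_vote(member_probs) -> tuple[np.ndarray, GradeLabel]:
    """Average member probability vectors and pick the winning grade.

    Inputs must each be a normalized 4-vector (error otherwise).  Exact
    argmax ties go to the more severe grade.
    """
    probs = np.atleast_2d(np.asarray(member_probs, dtype=float))
    if probs.shape[0] < 1 or probs.shape[1] != N_GRADES:
        raise ValueError(f"expected (k, {N_GRADES}) member probabilities")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(probs < -1e-12):
        raise ValueError("member probabilities must be normalized 4-vectors")
    mean = probs.mean(axis=0)
    winner = int(np.flatnonzero(mean == mean.max()).max())
    return mean, GradeLabel(winner)


class EnsembleDDIClassifier(BaseEstimator, ClassifierMixin):
    """k-member undersampling ensemble with soft voting.

    Parameters
    ----------
    n_members : int, default 5
        Ensemble size k.
    network : NetworkSpec or preset name, default "sim"
        Member architecture ("sim": hidden {1024, 512, 256, 128}, ReLU;
        "embedding": hidden {256, 128}, tanh; "small": {128, 64}, ReLU).
    undersample : bool, default True
        Split the majority grade across members.  With False every member
        sees the full training set (they still differ by seed).
    class_weight : {"inverse_frequency", None}, default "inverse_frequency"
        Per-subset loss weights w_c = N / (n_present * n_c), or all 1.
    tie_break : {"severe", "first"}, default "severe"
        Resolution of exact argmax ties in the vote.
    random_state : int, default 0
        Master seed; member i trains with seed random_state + i.

    Attributes (after fit)
    ----------------------
    members_ : list of trained member networks
    member_class_weights_ : (k, 4) array of the weights each member used
    partition_ : SubsetPartition or None (when undersampling)
    classes_ : array([0, 1, 2, 3])
    """

    def __init__(
        self,
        n_members: int = 5,
        network: NetworkSpec | str = "sim",
        undersample: bool = True,
        class_weight: str | None = "inverse_frequency",
        tie_break: str = "severe",
        random_state: int = 0,
    ):
        self.n_members = n_members
        self.network = network
        self.undersample = undersample
        self.class_weight = class_weight
        self.tie_break = tie_break
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        y = y.astype(int)
        present = np.unique(y)
        if len(present) < 2:
            raise ValueError("need at least two grade classes to train")
        if not set(present) <= set(range(N_GRADES)):
            raise ValueError(f"labels must be grade codes 0..3, got {present}")
        if self.tie_break not in ("severe", "first"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        spec = resolve_spec(self.network)

        if self.undersample and self.n_members >= 1:
            self.partition_ = partition_indices(
                y, self.n_members, self.random_state
            )
            subsets = self.partition_.subset_indices
        else:
            self.partition_ = None
            subsets = tuple(np.arange(len(y)) for _ in range(self.n_members))

        self.members_ = []
        member_weights = []
        for i, idx in enumerate(subsets):
            if self.class_weight == "inverse_frequency":
                w = weights_from_labels(y[idx])
            elif self.class_weight is None:
                w = np.ones(N_GRADES)
            else:
                raise ValueError(f"unknown class_weight {self.class_weight!r}")
            member_weights.append(w)
            logger.info(
                "member %d/%d: %d pairs, class counts %s, weights %s",
                i + 1,
                len(subsets),
                len(idx),
                [int(np.sum(y[idx] == g)) for g in range(N_GRADES)],
                np.round(w, 4).tolist(),
            )
            member = MLPSoftmax(spec, X.shape[1], seed=self.random_state + i)
            member.fit(X[idx], y[idx], class_weight=w)
            self.members_.append(member)
        self.member_class_weights_ = np.asarray(member_weights)
        self.classes_ = np.arange(N_GRADES)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = check_array(X, dtype=float)
        stacked = np.stack([m.predict_proba(X) for m in self.members_])
        return stacked.mean(axis=0)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        if self.tie_break == "severe":
            # argmax over reversed columns picks the largest index on ties
            return N_GRADES - 1 - np.argmax(probs[:, ::-1], axis=1)
        return np.argmax(probs, axis=1)


def train_ensemble(
    X,
    y,
    n_members: int = 5,
    network: NetworkSpec | str = "sim",
    seed: int = 0,
    undersample: bool = True,
    class_weight: str | None = "inverse_frequency",
) -> EnsembleDDIClassifier:
    """Functional wrapper over EnsembleDDIClassifier.fit."""
    return EnsembleDDIClassifier(
        n_members=n_members,
        network=network,
        undersample=undersample,
        class_weight=class_weight,
        random_state=seed,
    ).fit(X, y)


def single_model(network: NetworkSpec | str = "sim", seed: int = 0):
    """The non-ensemble baseline: one member, full data, unweighted loss."""
    return EnsembleDDIClassifier(
        n_members=1,
        network=network,
        undersample=False,
        class_weight=None,
        random_state=seed,
    )
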