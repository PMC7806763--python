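"""Random-forest classification of hallucination modality from edge weights.

A bagged ensemble of CART trees (Gini splits, ``m_try`` random candidate
features per split) with out-of-bag (OOB) evaluation: each subject is
predicted by majority vote of the trees whose bootstrap sample excluded
them, so no separate cross-validation loop is needed.  Variable importance
(VIMP) is Breiman permutation importance on the OOB samples, min-max
normalized to [0, 1].  Performance is reported as sensitivity and
specificity (per-class recall) and a weighted accuracy, the
prevalence-weighted average of class recalls (which corrects the plain
per-class average for unequal class sizes).

The bootstrap/OOB bookkeeping is owned by this module so that per-tree
in-bag indices are available for OOB permutation importance; the trees
themselves are scikit-learn ``DecisionTreeClassifier`` instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

#: Reference forest settings: 500 trees, m_try = round(sqrt(n_features)).
DEFAULT_N_TREES = 500


@dataclass
class ModalityRFResult:
    classes: list
    oob_predictions: np.ndarray
    oob_votes: np.ndarray            # subjects x classes vote counts
    confusion: np.ndarray            # true x predicted counts
    weighted_accuracy: float         # percent
    sensitivity: float               # percent, recall of the positive class
    specificity: float               # percent, recall of the negative class
    vimp: pd.Series                  # per feature, in [0, 1]


class OOBRandomForest(BaseEstimator, ClassifierMixin):
    """Bagged CART ensemble with out-of-bag prediction and permutation VIMP.

    Parameters
    ----------
    n_trees : int
        Number of bootstrap trees (default 500).
    m_try : int or None
        Candidate features per split; ``None`` means round(sqrt(n_features)).
    min_leaf : int
        Minimum samples per leaf (default 1).
    random_state : int
        Seeds the bootstrap draws, tree randomness and VIMP permutations.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, m_try: int | None = None,
                 min_leaf: int = 1, random_state: int = 0):
        self.n_trees = n_trees
        self.m_try = m_try
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if np.isnan(X).any():
            raise ValueError("missing feature values are not supported")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("labels contain a single class")
        counts = np.bincount(y_enc)
        if counts.min() < 2:
            raise ValueError("need at least 2 subjects per class")
        n, p = X.shape
        m_try = self.m_try if self.m_try is not None else max(1, round(np.sqrt(p)))
        if not 1 <= m_try <= p:
            raise ValueError(f"m_try={m_try} outside [1, {p}]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self.inbag_ = np.zeros((self.n_trees, n), dtype=bool)
        votes = np.zeros((n, len(self.classes_)))
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            self.inbag_[t, np.unique(idx)] = True
            tree = DecisionTreeClassifier(
                criterion="gini", max_features=m_try, min_samples_leaf=self.min_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[idx], y_enc[idx])
            self.trees_.append(tree)
            oob = ~self.inbag_[t]
            if oob.any():
                pred = tree.predict(X[oob])
                # trees trained on a bootstrap may miss a class; map back
                cls = np.arange(len(self.classes_))
                votes[np.flatnonzero(oob), :] += (pred[:, None] == cls[None, :])
        self.oob_vote_counts_ = votes
        self.oob_prediction_ = self.classes_[votes.argmax(axis=1)]
        self._X, self._y_enc = X, y_enc
        self.m_try_ = m_try
        self.vimp_ = self._permutation_vimp(rng)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        cls = np.arange(len(self.classes_))
        for tree in self.trees_:
            pred = tree.predict(X)
            votes += pred[:, None] == cls[None, :]
        return self.classes_[votes.argmax(axis=1)]

    def _permutation_vimp(self, rng) -> np.ndarray:
        """Breiman VIMP: mean over trees of the OOB error increase when one
        feature is permuted among that tree's OOB rows; min-max scaled."""
        X, y = self._X, self._y_enc
        n, p = X.shape
        raw = np.zeros(p)
        for t, tree in enumerate(self.trees_):
            oob = np.flatnonzero(~self.inbag_[t])
            if oob.size == 0:
                continue
            base = np.mean(tree.predict(X[oob]) == y[oob])
            Xp = X[oob].copy()
            for f in range(p):
                saved = Xp[:, f].copy()
                Xp[:, f] = saved[rng.permutation(oob.size)]
                raw[f] += base - np.mean(tree.predict(Xp) == y[oob])
                Xp[:, f] = saved
        raw /= len(self.trees_)
        lo, hi = raw.min(), raw.max()
        return (raw - lo) / (hi - lo) if hi > lo else np.zeros(p)


def evaluate(
    y_true,
    y_pred,
    positive_class,
    class_weights: str | dict = "prevalence",
) -> tuple[float, float, float]:
    """(weighted_accuracy, sensitivity, specificity), all in percent.

    Sensitivity is the recall of ``positive_class``, specificity the recall
    of the other class; weighted accuracy is sum_c w_c * recall_c with
    default weights w_c = class prevalence (custom weights via a dict
    {class: weight}).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("evaluate expects exactly 2 classes in y_true")
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    recalls, weights = {}, {}
    n = len(y_true)
    for c in classes:
        mask = y_true == c
        if not mask.any():
            raise ValueError(f"class {c!r} empty")
        recalls[c] = float(np.mean(y_pred[mask] == c))
        weights[c] = mask.sum() / n
    if class_weights != "prevalence":
        tot = sum(class_weights[c] for c in classes)
        weights = {c: class_weights[c] / tot for c in classes}
    negative = [c for c in classes if c != positive_class][0]
    wacc = 100.0 * sum(weights[c] * recalls[c] for c in classes)
    return wacc, 100.0 * recalls[positive_class], 100.0 * recalls[negative]


def classify_modality(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_class="visual",
    n_trees: int = DEFAULT_N_TREES,
    m_try: int | None = None,
    seed: int = 0,
) -> ModalityRFResult:
    """Fit the OOB forest on subject x edge features and summarize.

    Labels follow the convention that "visual" marks subjects with visual
    hallucinations (possibly plus auditory) and "auditory" auditory-only.
    """
    est = OOBRandomForest(n_trees=n_trees, m_try=m_try, random_state=seed)
    est.fit(features.to_numpy(dtype=float), labels.to_numpy())
    y = labels.to_numpy()
    pred = est.oob_prediction_
    classes = list(est.classes_)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for i, ct in enumerate(classes):
        for j, cp in enumerate(classes):
            conf[i, j] = int(np.sum((y == ct) & (pred == cp)))
    wacc, sens, spec = evaluate(y, pred, positive_class)
    return ModalityRFResult(
        classes=classes,
        oob_predictions=pred,
        oob_votes=est.oob_vote_counts_,
        confusion=conf,
        weighted_accuracy=wacc,
        sensitivity=sens,
        specificity=spec,
        vimp=pd.Series(est.vimp_, index=list(features.columns), name="vimp"),
    )
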