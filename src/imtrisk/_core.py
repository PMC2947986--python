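"""Internal scoring primitives shared by the selector and the evaluator.

The wrapper search and all deletion-based contribution scores need thousands
of cross-validated AUC evaluations of naive-Bayes models that differ only in
which features they include.  Because the naive factorization makes a model's
joint log-likelihood an exact sum of per-feature terms, each fold's
per-feature log-likelihood matrix is computed once and any feature subset is
then scored by summing rows -- bit-identical to refitting the reduced model.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .naive_bayes import MixedNaiveBayes

logger = logging.getLogger(__name__)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Probability that a random positive-class score exceeds a random
    negative-class score, with ties counting one half (midranks).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _roc_auc_rows(score_rows: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a (m, n) score matrix against one label vector."""
    y = labels.astype(bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(score_rows, axis=1)
    return (ranks[:, y].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _quantize(margins: np.ndarray) -> np.ndarray:
    """Round log-posterior margins to 1e-9 before ranking.

    Subjects with identical feature profiles must receive exactly tied scores
    no matter which algebraically equivalent path computed them (direct subset
    summation vs incremental parent-minus-feature), otherwise tie handling in
    the AUC would depend on ~1e-16 float residue.
    """
    return np.round(margins, 9)


def stratified_folds(y, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs; folds are reduced (with a warning) when a
    class has fewer subjects than requested folds."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("need at least 2 subjects per class for cross-validation")
    k_eff = min(k, min_count)
    if k_eff < k:
        logger.warning("reducing folds from %d to %d (smallest class has %d subjects)",
                       k, k_eff, min_count)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed % 2**31)
    return list(skf.split(np.zeros(len(y)), y))


class SubsetCV:
    """Cross-validated AUC of naive-Bayes models over arbitrary feature subsets.

    One stratified fold split (fixed by ``seed``) is built at construction and
    reused for every subset, so score differences between subsets reflect the
    features alone.
    """

    def __init__(self, X, y, k: int, seed: int, nb_params: dict | None = None):
        import pandas as pd

        self.feature_names = list(X.columns)
        self._index = {name: i for i, name in enumerate(self.feature_names)}
        y = np.asarray(pd.Series(y).to_numpy())
        self.folds = stratified_folds(y, k, seed)
        self.n_folds = len(self.folds)
        self._loglik = []   # per fold: (n_features, n_test, 2)
        self._prior = []    # per fold: (2,)
        self._y_test = []   # per fold: bool array (positive class)
        nb_params = nb_params or {}
        for train_idx, test_idx in self.folds:
            nb = MixedNaiveBayes(**nb_params).fit(X.iloc[train_idx], y[train_idx])
            self._loglik.append(nb.feature_log_likelihood(X.iloc[test_idx]))
            self._prior.append(nb.class_log_prior_)
            self._y_test.append(y[test_idx] == nb.classes_[1])

    def _idx(self, features) -> np.ndarray:
        return np.array([self._index[f] for f in features], dtype=int)

    def fold_sums(self, features) -> list[np.ndarray]:
        """Per-fold (n_test, 2) joint log-likelihoods of the given subset."""
        idx = self._idx(features)
        sums = []
        for f in range(self.n_folds):
            n_test = self._loglik[f].shape[1]
            s = np.tile(self._prior[f], (n_test, 1))
            if len(idx):
                s = s + self._loglik[f][idx].sum(axis=0)
            sums.append(s)
        return sums

    def fold_aucs(self, features) -> np.ndarray:
        aucs = np.empty(self.n_folds)
        for f, s in enumerate(self.fold_sums(features)):
            aucs[f] = roc_auc(_quantize(s[:, 1] - s[:, 0]), self._y_test[f])
        return aucs

    def score(self, features) -> float:
        """Mean per-fold AUC of the model restricted to ``features``."""
        return float(self.fold_aucs(features).mean())

    def pooled_auc(self, features) -> float:
        """AUC of the pooled out-of-fold posteriors (secondary summary)."""
        margins, labels = [], []
        for f, s in enumerate(self.fold_sums(features)):
            margins.append(_quantize(s[:, 1] - s[:, 0]))
            labels.append(self._y_test[f])
        return roc_auc(np.concatenate(margins), np.concatenate(labels))

    def score_removals(self, features, removable) -> np.ndarray:
        """Mean AUCs of the subsets obtained by removing each of ``removable``
        (singly) from ``features``; batched over folds."""
        base = self.fold_sums(features)
        rem_idx = self._idx(removable)
        out = np.zeros(len(rem_idx))
        for f in range(self.n_folds):
            reduced = base[f][None, :, :] - self._loglik[f][rem_idx]
            margins = _quantize(reduced[:, :, 1] - reduced[:, :, 0])
            out += _roc_auc_rows(margins, self._y_test[f])
        return out / self.n_folds


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) fanned out from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]
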