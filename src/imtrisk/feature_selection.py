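"""Two-stage selection of predictive variants.

Stage 1 (filter): rank features by entropy-based information gain with respect
to the low/high class labels and keep the top ``filter_k`` (default 40).
Numeric features are first supervised-discretized with entropy minimization
under the minimum-description-length (MDL) stopping rule.

Stage 2 (wrapper): best-first search over feature subsets in the backward
direction -- states are subsets of the filtered candidates, successors remove
one feature, and each state is scored by the stratified inner-CV (default
5-fold) AUC of the naive Bayes classifier.  An open list ordered by score
provides backtracking out of local optima; the search stops after
``stall_limit`` consecutive expansions without improving the best score (or
after ``max_expansions`` expansions).  All states share a single fold split so
their scores are directly comparable.

The comparison arm -- selecting SNPs by Bonferroni-corrected exact genotypic
test significance -- is also provided here.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._core import SubsetCV
from .association import bonferroni, exact_genotypic_test, genotype_table

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "information_gain",
    "mdl_discretize",
    "filter_top_k",
    "InformationGainFilter",
    "PredictiveSubsetSelector",
    "select_significant",
]

_EPS_SCORE = 1e-10


def _entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return np.array([(y == c).sum() for c in classes], dtype=float)


def mdl_discretize(values: np.ndarray, y: np.ndarray) -> list[float]:
    """Entropy-minimization cut points with the MDL acceptance criterion.

    Recursively splits the sorted value range at the boundary that minimizes
    the class-entropy of the partition, accepting a split only when its
    information gain exceeds the MDL coding cost; returns the accepted
    thresholds (possibly empty, meaning the feature collapses to one bin).
    """
    order = np.argsort(values, kind="stable")
    v, yy = np.asarray(values, dtype=float)[order], np.asarray(y)[order]
    classes = np.unique(yy)
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 4:
            return
        seg_v, seg_y = v[lo:hi], yy[lo:hi]
        total_counts = _class_counts(seg_y, classes)
        ent_s = _entropy(total_counts)
        if ent_s == 0.0:
            return
        best = None
        left_counts = np.zeros(len(classes))
        for i in range(n - 1):
            left_counts[np.searchsorted(classes, seg_y[i])] += 1
            if seg_v[i] == seg_v[i + 1]:
                continue
            right_counts = total_counts - left_counts
            n_l = i + 1
            e_l, e_r = _entropy(left_counts), _entropy(right_counts)
            ent_split = (n_l * e_l + (n - n_l) * e_r) / n
            if best is None or ent_split < best[0]:
                best = (ent_split, i, e_l, e_r,
                        _n_classes(left_counts), _n_classes(right_counts))
        if best is None:
            return
        ent_split, i, e_l, e_r, k_l, k_r = best
        gain = ent_s - ent_split
        k = _n_classes(total_counts)
        delta = np.log2(3.0**k - 2.0) - (k * ent_s - k_l * e_l - k_r * e_r)
        if gain <= (np.log2(n - 1) + delta) / n:
            return
        cuts.append((seg_v[i] + seg_v[i + 1]) / 2.0)
        recurse(lo, lo + i + 1)
        recurse(lo + i + 1, hi)

    recurse(0, len(v))
    return sorted(cuts)


def _n_classes(counts: np.ndarray) -> int:
    return int((counts > 0).sum())


def information_gain(feature, y, numeric: bool | None = None) -> float:
    """IG = H(class) - sum_v p(v) H(class | feature = v), in bits.

    Numeric features are MDL-discretized first; a feature that collapses to a
    single bin (or is constant) has zero gain.
    """
    feature = pd.Series(feature)
    y = np.asarray(pd.Series(y).to_numpy())
    classes = np.unique(y)
    if len(classes) < 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    if numeric is None:
        numeric = pd.api.types.is_float_dtype(feature)
    vals = feature.to_numpy()
    if numeric:
        cuts = mdl_discretize(vals.astype(float), y)
        if not cuts:
            return 0.0
        vals = np.searchsorted(np.asarray(cuts), vals.astype(float))
    h_class = _entropy(_class_counts(y, classes))
    total = len(y)
    cond = 0.0
    for v in pd.unique(vals):
        mask = vals == v
        cond += mask.sum() / total * _entropy(_class_counts(y[mask], classes))
    return max(float(h_class - cond), 0.0)


class InformationGainFilter(BaseEstimator):
    """Rank features by information gain and keep the top ``k``.

    Ties are broken by stable feature-name order so the ranking is
    deterministic.
    """

    def __init__(self, k: int = 40):
        self.k = k

    def fit(self, X: pd.DataFrame, y):
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[1]} available features")
        self.gains_ = {c: information_gain(X[c], y) for c in X.columns}
        order = sorted(self.gains_, key=lambda c: (-self.gains_[c], c))
        self.ranking_ = order
        self.selected_features_ = order[: self.k]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]


def filter_top_k(X: pd.DataFrame, y, k: int = 40) -> list[str]:
    return InformationGainFilter(k=k).fit(X, y).selected_features_


@dataclass
class SelectionResult:
    """Outcome of the filter-wrapper search."""

    selected_features: list[str]
    filter_ranking: dict[str, float]
    search_trace: list[tuple[tuple[str, ...], float]]
    inner_cv_auc: float
    config: dict = field(default_factory=dict)


class PredictiveSubsetSelector(BaseEstimator):
    """Filter-wrapper selection of a minimal predictive feature subset.

    Parameters
    ----------
    filter_k : int
        Number of top information-gain candidates passed to the wrapper.
        Capped at the number of searchable features.
    inner_folds : int
        Stratified CV folds used to score every candidate subset.
    stall_limit : int or None
        Consecutive non-improving expansions tolerated before stopping
        (None = no stall criterion).
    max_expansions : int or None
        Hard bound on node expansions (None = unbounded; with
        ``stall_limit=None`` too the search becomes exhaustive).
    forced_features : sequence
        Features present in every state and never removed (by default the
        conventional risk factors, when the caller passes them).
    random_state : int
        Fixes the inner fold split, making all state scores comparable and the
        whole search reproducible.
    alpha, sd_floor_frac, categories, categorical_features
        Forwarded to :class:`MixedNaiveBayes`.
    """

    def __init__(self, filter_k: int = 40, inner_folds: int = 5,
                 stall_limit: int | None = 5, max_expansions: int | None = 100,
                 forced_features=(), random_state: int = 0,
                 alpha: float = 1.0, sd_floor_frac: float = 1e-3,
                 categories: dict | None = None, categorical_features="infer"):
        self.filter_k = filter_k
        self.inner_folds = inner_folds
        self.stall_limit = stall_limit
        self.max_expansions = max_expansions
        self.forced_features = forced_features
        self.random_state = random_state
        self.alpha = alpha
        self.sd_floor_frac = sd_floor_frac
        self.categories = categories
        self.categorical_features = categorical_features

    def _nb_params(self) -> dict:
        return dict(alpha=self.alpha, sd_floor_frac=self.sd_floor_frac,
                    categories=self.categories,
                    categorical_features=self.categorical_features)

    def fit(self, X: pd.DataFrame, y):
        forced = [f for f in self.forced_features if f in X.columns]
        searchable = [c for c in X.columns if c not in set(forced)]
        if not searchable:
            raise ValueError("candidate feature set is empty")
        k = min(self.filter_k, len(searchable))
        ig = InformationGainFilter(k=k).fit(X[searchable], y)
        self.filter_ranking_ = ig.gains_
        candidates = ig.selected_features_

        scorer = SubsetCV(X[forced + candidates], y, k=self.inner_folds,
                          seed=self.random_state, nb_params=self._nb_params())
        cand_rank = {f: i for i, f in enumerate(candidates)}

        trace: list[tuple[tuple[str, ...], float]] = []
        evaluated: dict[frozenset, float] = {}

        def score_state(state: frozenset) -> float:
            feats = forced + [f for f in candidates if f in state]
            s = scorer.score(feats)
            evaluated[state] = s
            trace.append((tuple(sorted(state)), s))
            return s

        def batch_score(parent: frozenset, removables: list[str]) -> list[float]:
            feats = forced + [f for f in candidates if f in parent]
            aucs = scorer.score_removals(feats, removables)
            out = []
            for f, s in zip(removables, aucs):
                child = parent - {f}
                evaluated[child] = float(s)
                trace.append((tuple(sorted(child)), float(s)))
                out.append(float(s))
            return out

        def better(state_a, score_a, state_b, score_b) -> bool:
            """Tie rule: higher score, then smaller subset, then name order."""
            if score_a > score_b + _EPS_SCORE:
                return True
            if score_a < score_b - _EPS_SCORE:
                return False
            if len(state_a) != len(state_b):
                return len(state_a) < len(state_b)
            return tuple(sorted(state_a)) < tuple(sorted(state_b))

        full = frozenset(candidates)
        best_state, best_score = full, score_state(full)
        counter = 0
        heap: list = []

        def push(state, score):
            nonlocal counter
            key = tuple(sorted(cand_rank[f] for f in state))
            heapq.heappush(heap, (-score, len(state), key, counter, state))
            counter += 1

        push(full, best_score)
        stall = 0
        expansions = 0
        while heap:
            if self.max_expansions is not None and expansions >= self.max_expansions:
                break
            neg_s, _, _, _, state = heapq.heappop(heap)
            expansions += 1
            # score only successors not seen before: every state enters the
            # open list at most once
            removables = [f for f in sorted(state, key=cand_rank.get)
                          if (state - {f}) not in evaluated]
            improved = False
            if removables and len(state) > 1:
                scores = batch_score(state, removables)
                for f, s in zip(removables, scores):
                    child = state - {f}
                    if better(child, s, best_state, best_score):
                        if s > best_score + _EPS_SCORE:
                            improved = True
                        best_state, best_score = child, s
                    push(child, s)
            if improved:
                stall = 0
            else:
                stall += 1
                if self.stall_limit is not None and stall >= self.stall_limit:
                    break

        self.selected_features_ = forced + [f for f in candidates if f in best_state]
        self.search_trace_ = trace
        self.inner_cv_auc_ = best_score
        self.n_expansions_ = expansions
        self.result_ = SelectionResult(
            selected_features=list(self.selected_features_),
            filter_ranking=dict(self.filter_ranking_),
            search_trace=list(trace),
            inner_cv_auc=best_score,
            config=dict(filter_k=self.filter_k, inner_folds=self.inner_folds,
                        stall_limit=self.stall_limit,
                        max_expansions=self.max_expansions,
                        seed=self.random_state),
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]


def select_significant(genotypes: pd.DataFrame, y, alpha: float = 0.05,
                       m: int | None = None) -> list[str]:
    """SNPs whose Bonferroni-corrected exact genotypic p-value is <= alpha.

    ``m`` is the number of tests corrected for (default: the number of SNPs
    passed in).
    """
    if m is None:
        m = genotypes.shape[1]
    raw = np.array([
        exact_genotypic_test(genotype_table(genotypes[c], y)) for c in genotypes.columns
    ])
    corrected = bonferroni(raw, m=m)
    return [c for c, p in zip(genotypes.columns, corrected) if p <= alpha]
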