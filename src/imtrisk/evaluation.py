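"""Prediction-accuracy assessment.

Outer cross-validated AUC (default 10-fold, mean over folds), deletion-based
per-feature contributions, the pairwise epistasis interaction score

    I(x, y) = dAUC_{x,y} - dAUC_x - dAUC_y,

where dAUC is the drop in cross-validated AUC when the feature (or pair) is
deleted from the selected set and the model refit, a randomized-label null of
the full selection + evaluation pipeline, and independent-validation scoring
with frozen quantile cutoffs and a frozen model.

All deletion quantities within one report share a single outer fold split, so
differences reflect the deleted features only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import SubsetCV, roc_auc, spawn_seeds
from .naive_bayes import MixedNaiveBayes
from .stratify import QuantileRiskStratifier

logger = logging.getLogger(__name__)

__all__ = [
    "roc_auc",
    "EvaluationReport",
    "cross_validated_auc",
    "deletion_delta_auc",
    "percent_contributions",
    "interaction_score",
    "evaluation_report",
    "randomized_null",
    "validate_independent",
]


@dataclass
class EvaluationReport:
    outer_auc: float
    fold_aucs: list[float]
    pooled_auc: float
    selected_features: list[str]
    per_feature_delta: dict[str, float] = field(default_factory=dict)
    percent_contributions: dict[str, float] | None = None
    interaction_scores: dict[str, float] = field(default_factory=dict)
    per_fold_selected: list[list[str]] | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def _nb_params(kw: dict | None) -> dict:
    return dict(kw or {})


def cross_validated_auc(
    X: pd.DataFrame,
    y,
    features: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    selection_mode: str = "fixed_features",
    selector=None,
    nb_params: dict | None = None,
) -> EvaluationReport:
    """Stratified k-fold AUC of the naive Bayes model.

    ``selection_mode="fixed_features"`` evaluates the given feature list;
    ``"reselect_per_fold"`` clones ``selector`` (a
    :class:`~imtrisk.feature_selection.PredictiveSubsetSelector` or any
    estimator with ``selected_features_`` after ``fit``) inside each training
    fold, so feature selection never sees the held-out subjects.
    """
    from sklearn.base import clone

    from ._core import stratified_folds

    y = pd.Series(y).loc[X.index] if isinstance(y, pd.Series) else pd.Series(np.asarray(y), index=X.index)
    if selection_mode == "fixed_features":
        feats = list(features) if features is not None else list(X.columns)
        cv = SubsetCV(X[feats], y, k=k, seed=seed, nb_params=_nb_params(nb_params))
        fold_aucs = cv.fold_aucs(feats)
        return EvaluationReport(
            outer_auc=float(fold_aucs.mean()),
            fold_aucs=[float(a) for a in fold_aucs],
            pooled_auc=float(cv.pooled_auc(feats)),
            selected_features=feats,
            config={"outer_folds": len(fold_aucs), "seed": seed,
                    "selection_mode": selection_mode},
        )
    if selection_mode != "reselect_per_fold":
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    if selector is None:
        raise ValueError("reselect_per_fold requires a selector")

    yv = y.to_numpy()
    folds = stratified_folds(yv, k, seed)
    fold_seeds = spawn_seeds(seed, len(folds))
    fold_aucs, per_fold_selected = [], []
    pooled_scores, pooled_labels = [], []
    for (train_idx, test_idx), fseed in zip(folds, fold_seeds):
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr, y_te = yv[train_idx], yv[test_idx]
        sel = clone(selector)
        if "random_state" in sel.get_params():
            sel.set_params(random_state=fseed)
        sel.fit(X_tr, y_tr)
        feats = list(sel.selected_features_)
        nb = MixedNaiveBayes(**_nb_params(nb_params)).fit(X_tr[feats], y_tr)
        scores = nb.posterior(X_te[feats])
        fold_aucs.append(roc_auc(scores, y_te == nb.classes_[1]))
        per_fold_selected.append(feats)
        pooled_scores.append(scores)
        pooled_labels.append(y_te == nb.classes_[1])
    return EvaluationReport(
        outer_auc=float(np.mean(fold_aucs)),
        fold_aucs=[float(a) for a in fold_aucs],
        pooled_auc=float(roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))),
        selected_features=sorted(set().union(*map(set, per_fold_selected))),
        per_fold_selected=per_fold_selected,
        config={"outer_folds": len(folds), "seed": seed, "selection_mode": selection_mode},
    )


def deletion_delta_auc(X: pd.DataFrame, y, selected_features: list[str],
                       features_to_delete, k: int = 10, seed: int = 0,
                       nb_params: dict | None = None) -> float:
    """dAUC = AUC(selected) - AUC(selected minus deleted), same fold split."""
    delete = list(features_to_delete)
    if not set(delete) <= set(selected_features):
        raise ValueError("features_to_delete must be a subset of selected_features")
    if len(delete) == len(selected_features):
        raise ValueError("cannot delete every selected feature")
    cv = SubsetCV(X[list(selected_features)], y, k=k, seed=seed,
                  nb_params=_nb_params(nb_params))
    full = cv.score(list(selected_features))
    reduced = cv.score([f for f in selected_features if f not in set(delete)])
    return float(full - reduced)


def percent_contributions(deltas: dict[str, float]) -> dict[str, float]:
    """Normalize nonnegative deletion dAUCs to percentages summing to 100."""
    clipped = {f: max(d, 0.0) for f, d in deltas.items()}
    total = sum(clipped.values())
    if total <= 0:
        raise ValueError("all deletion contributions are nonpositive; "
                         "percent contributions are undefined")
    return {f: 100.0 * d / total for f, d in clipped.items()}


def interaction_score(X: pd.DataFrame, y, selected_features: list[str],
                      x_feat: str, y_feat: str, k: int = 10, seed: int = 0,
                      nb_params: dict | None = None) -> float:
    """I(x,y) = dAUC_{x,y} - dAUC_x - dAUC_y under one shared fold split."""
    if x_feat == y_feat:
        raise ValueError("interaction requires two distinct features")
    cv = SubsetCV(X[list(selected_features)], y, k=k, seed=seed,
                  nb_params=_nb_params(nb_params))
    return _interaction_from_cv(cv, list(selected_features), x_feat, y_feat)


def _interaction_from_cv(cv: SubsetCV, selected: list[str], x_feat: str, y_feat: str) -> float:
    full = cv.score(selected)
    d_x = full - cv.score([f for f in selected if f != x_feat])
    d_y = full - cv.score([f for f in selected if f != y_feat])
    d_xy = full - cv.score([f for f in selected if f not in (x_feat, y_feat)])
    return float(d_xy - d_x - d_y)


def evaluation_report(
    X: pd.DataFrame,
    y,
    selected_features: list[str],
    contribution_features: list[str] | None = None,
    interaction_pairs: list[tuple[str, str]] | None = None,
    k: int = 10,
    seed: int = 0,
    nb_params: dict | None = None,
    config: dict | None = None,
) -> EvaluationReport:
    """Outer-CV AUC plus per-feature deletion contributions and interaction
    scores, all computed on one shared fold split.

    ``contribution_features`` defaults to every selected feature; pass the SNP
    subset to reproduce a SNP-only contribution column.
    """
    selected = list(selected_features)
    cv = SubsetCV(X[selected], y, k=k, seed=seed, nb_params=_nb_params(nb_params))
    fold_aucs = cv.fold_aucs(selected)
    full = float(fold_aucs.mean())
    contrib_feats = list(contribution_features) if contribution_features is not None else selected
    reduced = cv.score_removals(selected, contrib_feats)
    deltas = {f: float(full - r) for f, r in zip(contrib_feats, reduced)}
    try:
        pct = percent_contributions(deltas)
    except ValueError:
        pct = None
    interactions = {}
    for x_feat, y_feat in interaction_pairs or []:
        interactions[f"{x_feat}|{y_feat}"] = _interaction_from_cv(cv, selected, x_feat, y_feat)
    return EvaluationReport(
        outer_auc=full,
        fold_aucs=[float(a) for a in fold_aucs],
        pooled_auc=float(cv.pooled_auc(selected)),
        selected_features=selected,
        per_feature_delta=deltas,
        percent_contributions=pct,
        interaction_scores=interactions,
        config=dict(config or {}, outer_folds=len(fold_aucs), seed=seed),
    )


def predictive_snp_table(
    report: EvaluationReport,
    genotypes: pd.DataFrame,
    y,
    m: int | None = None,
    annotations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-SNP summary of a fitted panel: exact-test p-values (raw and
    Bonferroni-corrected) next to the percent contribution to the panel's
    cross-validated AUC, sorted by contribution — the standard presentation of
    a predictive SNP panel."""
    from .association import association_table

    snps = [f for f in report.selected_features if f in genotypes.columns]
    stats = association_table(genotypes[snps], y, m=m).set_index("snp_id")
    pct = report.percent_contributions or {}
    out = pd.DataFrame({
        "snp_id": snps,
        "annotation": [(annotations or {}).get(s, "") for s in snps],
        "p_exact": [stats.loc[s, "p_raw"] for s in snps],
        "p_bonferroni": [stats.loc[s, "p_bonferroni"] for s in snps],
        "pct_auc": [pct.get(s, float("nan")) for s in snps],
    })
    return out.sort_values("pct_auc", ascending=False, ignore_index=True)


def randomized_null(
    X: pd.DataFrame,
    class_sizes: tuple[int, int],
    n_reps: int = 100,
    seed: int = 0,
    selector=None,
    k: int = 10,
    nb_params: dict | None = None,
) -> dict:
    """Null distribution of pipeline AUC under random low/high labels.

    For each repetition, ``class_sizes`` subjects are drawn at random from
    ``X`` (independently of any phenotype) and labeled low/high; the full
    pipeline -- per-fold feature selection when ``selector`` is given, then
    stratified outer CV -- is run and the mean AUC recorded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_low, n_high = class_sizes
    if n_low + n_high > len(X):
        raise ValueError("class sizes exceed the number of subjects")
    rng = np.random.default_rng(seed)
    rep_seeds = spawn_seeds(seed, n_reps)
    aucs = np.empty(n_reps)
    for r in range(n_reps):
        chosen = rng.choice(len(X), size=n_low + n_high, replace=False)
        y = np.zeros(n_low + n_high, dtype=int)
        y[rng.choice(n_low + n_high, size=n_high, replace=False)] = 1
        X_r = X.iloc[chosen]
        if selector is not None:
            rep = cross_validated_auc(X_r, y, k=k, seed=rep_seeds[r],
                                      selection_mode="reselect_per_fold",
                                      selector=selector, nb_params=nb_params)
        else:
            rep = cross_validated_auc(X_r, y, k=k, seed=rep_seeds[r],
                                      nb_params=nb_params)
        aucs[r] = rep.outer_auc
    return {"aucs": aucs, "mean_auc": float(aucs.mean()), "max_auc": float(aucs.max())}


def validate_independent(
    model: MixedNaiveBayes,
    new_features: pd.DataFrame,
    new_values: pd.Series,
    cutoffs: tuple[float, float],
    q: float,
    training_ids,
    training_auc: float | None = None,
) -> dict:
    """Score an independent cohort with a frozen model and frozen IMT cutoffs.

    New subjects are labeled low/high by the exact cutoff values learned on the
    original cohort (no re-quantiling); subject overlap with the training
    cohort is rejected.
    """
    overlap = set(new_features.index) & set(training_ids)
    if overlap:
        raise ValueError(f"validation subjects overlap the training cohort: "
                         f"{sorted(overlap)[:5]}...")
    strat = QuantileRiskStratifier(q=q)
    strat.cutoff_low_, strat.cutoff_high_ = cutoffs
    labels = strat.transform(new_values.loc[new_features.index])
    y = labels.binary()
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValueError("no validation subject falls in one of the risk classes")
    feats = new_features.loc[y.index, model.feature_names_]
    scores = model.posterior(feats)
    auc = roc_auc(scores, y.to_numpy() == 1)
    out = {"auc": float(auc), "n_low": int((y == 0).sum()), "n_high": int((y == 1).sum())}
    if training_auc is not None:
        out["auc_drop"] = float(training_auc - auc)
    return out
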