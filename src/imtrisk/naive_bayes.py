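"""Mixed categorical/Gaussian naive Bayes risk classifier.

The posterior for risk class R given predictors P = (S_1..S_l, C_1..C_m) is

    P(R | P)  proportional to  P(R) * prod_i P(P_i | R),

i.e. class prior times a product of per-feature class-conditional likelihoods,
assuming conditional independence of the predictors given the class.  SNP
genotypes (and binary risk factors) are unordered categories with
Laplace-smoothed conditional probability tables; numeric risk factors get
per-class Gaussian densities with a floored standard deviation.  All
computation is in log space, so products over many near-zero likelihoods never
underflow; the class-independent scaling factor cancels on normalization.

Class priors are proportional to the training class counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["MixedNaiveBayes"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X))


class MixedNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes over mixed categorical and numeric features.

    Parameters
    ----------
    alpha : float
        Laplace smoothing pseudo-count for categorical conditional tables.
    sd_floor_frac : float
        Per-feature Gaussian SD floor, as a fraction of the feature's global
        (class-pooled) training SD; if the global SD is zero the floor is
        ``sd_floor_frac`` itself.  Prevents infinite densities at
        near-constant features.
    categorical_features : list of column names, "infer", or None
        With "infer" (default), integer- and boolean-typed columns are treated
        as categorical and float columns as Gaussian.
    categories : dict, optional
        Mapping column -> explicit category list (e.g. genotypes always have
        the three levels 0/1/2 even if one is absent from a small training
        class).  Columns not listed use the observed training levels.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted; index 1 = positive).
    class_log_prior_ : ndarray, shape (2,)
    categorical_tables_ : dict col -> {"levels": list, "log_prob": (2, K) array,
        "log_floor": (2,) array for unseen levels}
    gaussian_params_ : dict col -> {"mean": (2,), "sd": (2,)}
    feature_names_ : ordered list of feature columns the model expects.
    """

    def __init__(self, alpha: float = 1.0, sd_floor_frac: float = 1e-3,
                 categorical_features="infer", categories: dict | None = None):
        self.alpha = alpha
        self.sd_floor_frac = sd_floor_frac
        self.categorical_features = categorical_features
        self.categories = categories

    # ------------------------------------------------------------------ fit
    def _split_kinds(self, X: pd.DataFrame) -> list:
        if self.categorical_features == "infer":
            return [c for c in X.columns
                    if pd.api.types.is_integer_dtype(X[c]) or pd.api.types.is_bool_dtype(X[c])]
        return [c for c in (self.categorical_features or []) if c in X.columns]

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(pd.Series(y).to_numpy())
        if X.isna().any().any():
            raise ValueError("training features contain missing values (complete-case contract)")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError(
                f"need subjects in both classes; only class {self.classes_[0]!r} present"
            )
        if len(self.classes_) != 2:
            raise ValueError("binary low/high classification expected")
        self.class_log_prior_ = np.log(counts / counts.sum())
        self.feature_names_ = list(X.columns)
        cat_cols = set(self._split_kinds(X))
        declared = self.categories or {}

        self.categorical_tables_ = {}
        self.gaussian_params_ = {}
        masks = [y == c for c in self.classes_]
        for col in X.columns:
            vals = X[col].to_numpy()
            if col in cat_cols:
                observed = pd.unique(vals).tolist()
                declared_levels = declared.get(col)
                if declared_levels is None:
                    levels = sorted(observed)
                else:
                    levels = sorted(set(declared_levels) | set(observed))
                K = len(levels)
                level_index = {lv: i for i, lv in enumerate(levels)}
                log_prob = np.empty((2, K))
                log_floor = np.empty(2)
                for ci, m in enumerate(masks):
                    sub = vals[m]
                    cnt = np.zeros(K)
                    for v in sub:
                        cnt[level_index[v]] += 1
                    denom = len(sub) + self.alpha * K
                    log_prob[ci] = np.log((cnt + self.alpha) / denom)
                    log_floor[ci] = np.log(self.alpha / denom)
                self.categorical_tables_[col] = {
                    "levels": levels, "log_prob": log_prob, "log_floor": log_floor,
                }
            else:
                fvals = vals.astype(float)
                global_sd = float(fvals.std(ddof=0))
                floor = self.sd_floor_frac * (global_sd if global_sd > 0 else 1.0)
                mean = np.array([fvals[m].mean() for m in masks])
                sd = np.array([max(fvals[m].std(ddof=0), floor) for m in masks])
                self.gaussian_params_[col] = {"mean": mean, "sd": sd}
        return self

    # --------------------------------------------------------------- scoring
    def feature_log_likelihood(self, X) -> np.ndarray:
        """Per-feature class-conditional log-likelihoods.

        Returns an array of shape (n_features, n_samples, 2) in the order of
        ``feature_names_``; summing over any feature subset plus the log prior
        gives that reduced model's joint log-likelihood exactly (the naive
        factorization).  This is the primitive the wrapper search and the
        deletion-based contribution scores build on.
        """
        X = _as_frame(X)
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        n = len(X)
        out = np.empty((len(self.feature_names_), n, 2))
        for fi, col in enumerate(self.feature_names_):
            vals = X[col].to_numpy()
            if pd.isna(vals).any():
                raise ValueError(f"feature {col!r} has missing values (complete-case contract)")
            if col in self.categorical_tables_:
                tab = self.categorical_tables_[col]
                level_index = {lv: i for i, lv in enumerate(tab["levels"])}
                idx = np.array([level_index.get(v, -1) for v in vals])
                known = idx >= 0
                for ci in range(2):
                    out[fi, known, ci] = tab["log_prob"][ci][idx[known]]
                    out[fi, ~known, ci] = tab["log_floor"][ci]
            else:
                par = self.gaussian_params_[col]
                fvals = vals.astype(float)
                for ci in range(2):
                    sd, mu = par["sd"][ci], par["mean"][ci]
                    out[fi, :, ci] = (
                        -0.5 * ((fvals - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI
                    )
        return out

    def joint_log_likelihood(self, X) -> np.ndarray:
        return self.class_log_prior_ + self.feature_log_likelihood(X).sum(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def posterior(self, X) -> np.ndarray:
        """Probability of the high-risk (positive, classes_[1]) class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        # exact posterior tie goes to the low-risk class
        post = self.posterior(X)
        return np.where(post > 0.5, self.classes_[1], self.classes_[0])

    # --------------------------------------------------------- serialization
    def to_json(self, path=None) -> str:
        doc = {
            "alpha": self.alpha,
            "sd_floor_frac": self.sd_floor_frac,
            "classes": [_jsonable(c) for c in self.classes_],
            "class_log_prior": self.class_log_prior_.tolist(),
            "feature_names": self.feature_names_,
            "categorical_tables": {
                c: {"levels": [_jsonable(l) for l in t["levels"]],
                    "log_prob": t["log_prob"].tolist(),
                    "log_floor": t["log_floor"].tolist()}
                for c, t in self.categorical_tables_.items()
            },
            "gaussian_params": {
                c: {"mean": p["mean"].tolist(), "sd": p["sd"].tolist()}
                for c, p in self.gaussian_params_.items()
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MixedNaiveBayes":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        model = cls(alpha=doc["alpha"], sd_floor_frac=doc["sd_floor_frac"])
        model.classes_ = np.asarray(doc["classes"])
        model.class_log_prior_ = np.asarray(doc["class_log_prior"])
        model.feature_names_ = list(doc["feature_names"])
        model.categorical_tables_ = {
            c: {"levels": t["levels"], "log_prob": np.asarray(t["log_prob"]),
                "log_floor": np.asarray(t["log_floor"])}
            for c, t in doc["categorical_tables"].items()
        }
        model.gaussian_params_ = {
            c: {"mean": np.asarray(p["mean"]), "sd": np.asarray(p["sd"])}
            for c, p in doc["gaussian_params"].items()
        }
        return model


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
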