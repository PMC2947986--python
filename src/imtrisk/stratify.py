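"""Extreme-quantile risk-class construction.

A continuous phenotype (IMT level at a visit, or its 6-year change) is turned
into a binary classification problem by comparing the subjects in the lowest
q-fraction of the pooled distribution (low-risk class) against those in the
highest q-fraction (high-risk class); everyone in between is excluded.  No
age or sex stratification is applied: the distribution is pooled.

Class membership is rank-based and therefore invariant under strictly
increasing transforms of the phenotype.  Cutoff *values* (the empirical q and
1-q quantiles, linear interpolation) are reported alongside so that an
independent cohort can be labeled with frozen cutoffs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["RiskClassLabels", "QuantileRiskStratifier", "progression",
           "assign_risk_classes", "exclude_near_cutoff"]

LOW, HIGH, EXCLUDED = "low", "high", "excluded"


@dataclass
class RiskClassLabels:
    """Per-subject low/high/excluded assignment with its defining quantile."""

    labels: pd.Series  # values in {"low", "high", "excluded"}
    q: float
    cutoff_low: float
    cutoff_high: float
    target_kind: str = "progression"  # baseline | followup | progression

    @property
    def low_ids(self) -> pd.Index:
        return self.labels.index[self.labels == LOW]

    @property
    def high_ids(self) -> pd.Index:
        return self.labels.index[self.labels == HIGH]

    @property
    def analysis_ids(self) -> pd.Index:
        return self.labels.index[self.labels != EXCLUDED]

    def binary(self) -> pd.Series:
        """0/1 labels (high = 1) for the non-excluded subjects."""
        kept = self.labels[self.labels != EXCLUDED]
        return (kept == HIGH).astype(int)

    def to_files(self, table_path, sidecar_path=None) -> None:
        self.labels.rename("label").to_csv(table_path, sep="\t")
        if sidecar_path is not None:
            meta = {k: v for k, v in asdict(self).items() if k != "labels"}
            Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def progression(imt_baseline: pd.Series, imt_followup: pd.Series) -> pd.Series:
    """Follow-up minus baseline IMT; subjects missing either visit are dropped."""
    change = imt_followup - imt_baseline
    complete = change.dropna()
    n_dropped = len(change) - len(complete)
    if n_dropped:
        logger.info("progression: dropped %d subjects with a missing visit", n_dropped)
    return complete.rename("imt_progression")


class QuantileRiskStratifier(BaseEstimator):
    """Labels subjects as low/high/excluded at quantile ``q``.

    ``fit`` learns the empirical cutoffs from a phenotype series; ``transform``
    labels (possibly new) subjects with the *frozen* cutoffs, which is how an
    independent validation cohort is classified.  ``fit_transform`` applies the
    rank-based tie rule on the fitting data itself: the target class size is
    floor(q*n) on each side, subjects strictly beyond a cutoff enter first,
    and cutoff-equal subjects are admitted in stable input order until the
    target is reached.

    Parameters
    ----------
    q : float
        Tail fraction in (0, 0.5).
    target_kind : str
        Which phenotype the values represent (metadata only).
    """

    def __init__(self, q: float = 0.15, target_kind: str = "progression"):
        self.q = q
        self.target_kind = target_kind

    def _validate(self, values: pd.Series) -> pd.Series:
        if not 0.0 < self.q < 0.5:
            raise ValueError(f"q must be in (0, 0.5), got {self.q}")
        values = pd.Series(values).dropna()
        if values.nunique() < 2:
            raise ValueError("phenotype values are all equal; no quantile separation")
        if len(values) < 2 / self.q:
            raise ValueError(f"need at least {int(np.ceil(2 / self.q))} subjects for q={self.q}")
        return values

    def fit(self, values: pd.Series, y=None):
        values = self._validate(values)
        self.cutoff_low_ = float(np.quantile(values, self.q))
        self.cutoff_high_ = float(np.quantile(values, 1.0 - self.q))
        self.n_fit_ = len(values)
        return self

    def transform(self, values: pd.Series) -> RiskClassLabels:
        """Label by the frozen cutoff values (value <= low cutoff -> low, etc.)."""
        values = pd.Series(values).dropna()
        labels = pd.Series(EXCLUDED, index=values.index, name="label")
        labels[values <= self.cutoff_low_] = LOW
        labels[values >= self.cutoff_high_] = HIGH
        return RiskClassLabels(labels, self.q, self.cutoff_low_, self.cutoff_high_,
                               self.target_kind)

    def fit_transform(self, values: pd.Series, y=None) -> RiskClassLabels:
        values_c = self._validate(values)
        self.fit(values_c)
        n = len(values_c)
        k = int(np.floor(self.q * n))
        order = np.argsort(values_c.to_numpy(), kind="stable")
        labels = pd.Series(EXCLUDED, index=values_c.index, name="label")
        labels.iloc[order[:k]] = LOW
        labels.iloc[order[n - k:]] = HIGH
        return RiskClassLabels(labels, self.q, self.cutoff_low_, self.cutoff_high_,
                               self.target_kind)


def assign_risk_classes(
    values: pd.Series, q: float, target_kind: str = "progression"
) -> RiskClassLabels:
    """Functional wrapper over :class:`QuantileRiskStratifier.fit_transform`."""
    return QuantileRiskStratifier(q=q, target_kind=target_kind).fit_transform(values)


def exclude_near_cutoff(
    values: pd.Series, labels: RiskClassLabels, delta: float = 0.02
) -> RiskClassLabels:
    """Relabel low/high subjects whose value lies within ``delta`` of the nearer cutoff.

    Mitigates sensitivity of extreme-class membership to the exact cutoff by
    removing subjects at or close to the quantile boundary.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    new = labels.labels.copy()
    vals = pd.Series(values).reindex(new.index)
    near_low = (new == LOW) & ((labels.cutoff_low - vals).abs() < delta)
    near_high = (new == HIGH) & ((vals - labels.cutoff_high).abs() < delta)
    new[near_low | near_high] = EXCLUDED
    return RiskClassLabels(new, labels.q, labels.cutoff_low, labels.cutoff_high,
                           labels.target_kind)
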