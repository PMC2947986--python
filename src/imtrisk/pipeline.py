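"""End-to-end experiment orchestration.

Ties the stages together: complete-case subject selection, extreme-quantile
stratification of the chosen phenotype target at each q, construction of the
four comparison arms (conventional risk factors alone; CRFs plus the
established SNP panel; CRFs plus Bonferroni-significant SNPs; CRFs plus
wrapper-selected predictive SNPs), outer cross-validated evaluation, and the
AUC-versus-q curve.  Subjects held out by the complete-case filter supply the
independent validation set for any final model whose SNPs they are complete
on.  All randomness fans out from a single master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import spawn_seeds
from .evaluation import EvaluationReport, cross_validated_auc, evaluation_report
from .feature_selection import PredictiveSubsetSelector, select_significant
from .simulate import Cohort
from .stratify import QuantileRiskStratifier, exclude_near_cutoff, progression

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ARMS", "complete_case_filter", "target_values",
            "build_validation_pool", "run_experiment"]

ARMS = ("crf_only", "established_plus_crf", "significant_plus_crf", "predictive_plus_crf")


@dataclass
class RunConfig:
    """Configuration of one experiment (one target, several q values, one arm)."""

    target_kind: str = "progression"  # baseline | followup | progression
    q_list: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)
    arm: str = "predictive_plus_crf"
    filter_k: int = 40
    inner_folds: int = 5
    outer_folds: int = 10
    stall_limit: int = 5
    max_expansions: int = 100
    alpha: float = 0.05          # significance level of the comparison arm
    force_crfs: bool = True      # CRFs always in the model; only SNPs searched
    near_cutoff_delta: float = 0.0
    nested_selection: bool = True  # reselect features inside each outer fold
    seed: int = 0

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        for q in self.q_list:
            if not 0.0 < q < 0.5:
                raise ValueError("q values must lie in (0, 0.5)")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def target_values(cohort: Cohort, target_kind: str) -> pd.Series:
    if target_kind == "baseline":
        return cohort.imt_baseline.dropna()
    if target_kind == "followup":
        return cohort.imt_followup.dropna()
    if target_kind == "progression":
        return progression(cohort.imt_baseline, cohort.imt_followup)
    raise ValueError(f"unknown target_kind {target_kind!r}")


def complete_case_filter(cohort: Cohort, required_snps: list[str] | None = None,
                         target_kind: str = "progression") -> tuple[Cohort, Cohort]:
    """Split a cohort into complete-case subjects and a held-out pool.

    A subject is complete when every required SNP, every risk factor and every
    phenotype visit the target needs are observed.  Held-out subjects are not
    discarded: they later form the independent validation set for any model
    whose features they are complete on.
    """
    snps = list(required_snps) if required_snps is not None else list(cohort.genotypes.columns)
    ok = ~cohort.genotypes[snps].isna().any(axis=1)
    ok &= ~cohort.risk_factors.isna().any(axis=1)
    ok &= cohort.imt_baseline.notna()
    if target_kind in ("followup", "progression"):
        ok &= cohort.imt_followup.notna()
    logger.info("complete-case filter: %d of %d subjects complete on %d SNPs",
                int(ok.sum()), len(ok), len(snps))

    def _subset(mask) -> Cohort:
        return Cohort(cohort.genotypes[mask], cohort.risk_factors[mask],
                      cohort.imt_baseline[mask], cohort.imt_followup[mask],
                      panel=cohort.panel)

    return _subset(ok), _subset(~ok)


def build_validation_pool(heldout: Cohort, model_snps: list[str],
                          target_kind: str = "baseline") -> Cohort:
    """Held-out subjects complete on a final model's SNPs (and phenotype)."""
    complete, _ = complete_case_filter(heldout, required_snps=model_snps,
                                       target_kind=target_kind)
    return complete


def _arm_features(arm: str, X_geno: pd.DataFrame, crf_names: list[str],
                  established: list[str], y, config: RunConfig,
                  seed: int) -> tuple[list[str] | None, object | None]:
    """Fixed feature list, or a selector to clone per fold, for one arm."""
    if arm == "crf_only":
        return crf_names, None
    if arm == "established_plus_crf":
        present = [s for s in established if s in X_geno.columns]
        return crf_names + present, None
    if arm == "significant_plus_crf":
        return None, _SignificantSelector(crf_names=crf_names, alpha=config.alpha,
                                          snp_names=list(X_geno.columns))
    snp_cats = {c: (0, 1, 2) for c in X_geno.columns}
    forced = crf_names if config.force_crfs else ()
    selector = PredictiveSubsetSelector(
        filter_k=config.filter_k, inner_folds=config.inner_folds,
        stall_limit=config.stall_limit, max_expansions=config.max_expansions,
        forced_features=forced, random_state=seed, categories=snp_cats,
    )
    return None, selector


class _SignificantSelector:
    """Per-fold exact-test SNP selection (sklearn-clonable)."""

    def __init__(self, crf_names=(), alpha=0.05, snp_names=(), random_state=0):
        self.crf_names = crf_names
        self.alpha = alpha
        self.snp_names = snp_names
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"crf_names": self.crf_names, "alpha": self.alpha,
                "snp_names": self.snp_names, "random_state": self.random_state}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        snps = [s for s in self.snp_names if s in X.columns]
        sig = select_significant(X[snps], y, alpha=self.alpha)
        self.selected_features_ = list(self.crf_names) + sig
        return self


def vcf_to_genotypes(path) -> pd.DataFrame:
    """Import a VCF as a subjects x SNPs table coded by alternate-allele count.

    Thin adapter for candidate-panel VCFs: biallelic sites only; missing or
    half-called genotypes become NA; the SNP identifier is the VCF ID field
    (falling back to chrom:pos).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        sid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = variant.gt_types.astype(float)
        g[g == 3] = np.nan
        cols[sid] = g
    return pd.DataFrame(cols, index=pd.Index(samples, name="subject_id"))


def run_experiment(config: RunConfig, cohort: Cohort,
                   established: list[str] | None = None) -> dict:
    """Run one arm across all q values; returns per-q reports and the AUC curve.

    The cohort is complete-case filtered first; quantile cutoffs are computed
    on the analysis subset.  Every report embeds the full configuration.
    """
    if established is None:
        established = cohort.established_snps()
    analysis, heldout = complete_case_filter(cohort, target_kind=config.target_kind)
    values = target_values(analysis, config.target_kind)
    geno = analysis.genotypes.loc[values.index].astype(int)
    crf = analysis.risk_factors.loc[values.index]
    X = pd.concat([crf, geno], axis=1)
    crf_names = list(crf.columns)

    q_seeds = spawn_seeds(config.seed, len(config.q_list))
    reports: dict[float, EvaluationReport] = {}
    curve_rows = []
    for q, q_seed in zip(config.q_list, q_seeds):
        strat = QuantileRiskStratifier(q=q, target_kind=config.target_kind)
        labels = strat.fit_transform(values)
        if config.near_cutoff_delta > 0:
            labels = exclude_near_cutoff(values, labels, config.near_cutoff_delta)
        y = labels.binary()
        if y.nunique() < 2:
            raise ValueError(f"empty risk class at q={q}")
        X_q = X.loc[y.index]
        fixed, selector = _arm_features(config.arm, geno, crf_names, established,
                                        y, config, q_seed)
        if selector is not None and config.nested_selection:
            rep = cross_validated_auc(X_q, y, k=config.outer_folds, seed=q_seed,
                                      selection_mode="reselect_per_fold",
                                      selector=selector)
        else:
            if selector is not None:
                feats = selector.fit(X_q, y.to_numpy()).selected_features_
            else:
                feats = fixed
            snp_feats = [f for f in feats if f not in set(crf_names)]
            rep = evaluation_report(X_q, y, feats,
                                    contribution_features=snp_feats or None,
                                    k=config.outer_folds, seed=q_seed)
        rep.config.update(config.to_dict(), q=q,
                          cutoff_low=labels.cutoff_low, cutoff_high=labels.cutoff_high,
                          n_low=int((y == 0).sum()), n_high=int((y == 1).sum()))
        reports[q] = rep
        curve_rows.append({"q": q, "arm": config.arm, "auc": rep.outer_auc})
        logger.info("arm=%s q=%.2f AUC=%.3f", config.arm, q, rep.outer_auc)
    return {
        "reports": reports,
        "auc_curve": pd.DataFrame(curve_rows),
        "heldout": heldout,
        "config": config,
    }
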