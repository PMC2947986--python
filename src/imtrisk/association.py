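"""Single-SNP association testing and supporting statistics.

The genotypic association of one SNP with the low/high risk classes is tested
on the 2x3 contingency table of genotype counts per class, using the exact
conditional test with fixed margins: the p-value is the total hypergeometric
probability of every table with the same margins whose point probability does
not exceed that of the observed table (Fisher's point-probability ordering,
two-sided by construction).  The table space is enumerated in full over the
two free cells, so the p-value is exact at any cohort size used here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = ["genotype_table", "exact_genotypic_test", "bonferroni",
           "pearson_r_test", "ks_D", "association_table"]

# relative slack on log point probabilities when comparing against the
# observed table (guards against round-off excluding genuinely tied tables)
_LOG_TOL = 1e-7


def genotype_table(genotypes, y) -> np.ndarray:
    """2x3 counts of genotypes 0/1/2 among low (row 0) and high (row 1) subjects."""
    g = np.asarray(pd.Series(genotypes).to_numpy())
    y = np.asarray(pd.Series(y).to_numpy()).astype(bool)
    table = np.zeros((2, 3), dtype=int)
    for row, mask in enumerate((~y, y)):
        sub = g[mask]
        for level in range(3):
            table[row, level] = int((sub == level).sum())
    return table


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def exact_genotypic_test(table) -> float:
    """Exact conditional p-value for a 2x3 genotype-by-class table."""
    t = np.asarray(table)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 contingency table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    t = t.astype(np.int64)
    n = int(t.sum())
    if n < 1:
        raise ValueError("total count must be >= 1")
    r0 = int(t[0].sum())
    c = t.sum(axis=0)
    # degenerate margins: a single possible table
    if r0 == 0 or r0 == n or (c > 0).sum() <= 1:
        return 1.0

    a = np.arange(c[0] + 1)[:, None]  # count of genotype 0 in row 0
    b = np.arange(c[1] + 1)[None, :]  # count of genotype 1 in row 0
    rem = r0 - a - b                  # count of genotype 2 in row 0
    valid = (rem >= 0) & (rem <= c[2])
    rem_safe = np.where(valid, rem, 0)
    logp = (
        _log_binom(c[0], a) + _log_binom(c[1], b) + _log_binom(c[2], rem_safe)
        - _log_binom(n, r0)
    )
    logp = np.where(valid, logp, -np.inf)
    logp_obs = logp[t[0, 0], t[0, 1]]
    extreme = logp <= logp_obs + _LOG_TOL * abs(logp_obs) + 1e-12
    p = float(np.exp(logp[valid & extreme]).sum())
    return min(p, 1.0)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Multiply each p-value by the number of tests ``m``, truncating at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(p * m, 1.0)


def pearson_r_test(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ks_D(sample_a, sample_b) -> float:
    """Kolmogorov-Smirnov D: maximal vertical ECDF distance between two samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.ks_2samp(a, b).statistic)


def association_table(genotypes: pd.DataFrame, y, m: int | None = None,
                      target_kind: str = "progression", q: float | None = None
                      ) -> pd.DataFrame:
    """Per-SNP raw and Bonferroni-corrected exact p-values (exportable table)."""
    if m is None:
        m = genotypes.shape[1]
    raw = np.array([exact_genotypic_test(genotype_table(genotypes[c], y))
                    for c in genotypes.columns])
    out = pd.DataFrame({
        "snp_id": list(genotypes.columns),
        "p_raw": raw,
        "p_bonferroni": bonferroni(raw, m=m),
    })
    out["target_kind"] = target_kind
    if q is not None:
        out["q"] = q
    return out
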