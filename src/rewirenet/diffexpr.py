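"""Paired differential expression and phenotype-association analyses.

Expression changes between conditions are assessed per gene with Student's
paired t-test across individuals and Bonferroni correction over the genes
actually tested.  Two follow-up analyses target genes whose *modest* changes
matter: a filter for small-but-consistent fold changes with appreciable
inter-individual variance, and correlation of each gene's per-individual
expression change with a quantitative phenotype (a caspase-activity-like
cell-death readout), including an extreme-group comparison of the phenotype
between the individuals with the largest and smallest responses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import fold_change_matrix
from .synthgen import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "paired_t_tests",
    "classify_modest_changes",
    "phenotype_correlation",
    "extreme_group_test",
]


def paired_t_tests(study: ExpressionStudy, baseline_label: str,
                   stress_label: str) -> pd.DataFrame:
    """Per-gene paired t-test of stress vs baseline with Bonferroni control.

    For each gene the per-individual differences d give
    t = mean(d) / (sd(d)/sqrt(n)), df = n − 1, two-sided p, and
    p_bonferroni = min(1, m·p) with m the number of genes tested.
    Genes with zero-variance differences get t = 0, p = 1 when the mean
    difference is also zero; a nonzero mean with zero variance is an error.
    """
    fc = fold_change_matrix(study, baseline_label, stress_label)
    n = fc.shape[1]
    if n < 3:
        raise ValueError(f"need >=3 paired individuals, got {n}")
    d = fc.to_numpy()
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    var = sd**2
    zero = sd == 0
    bad = zero & (mean != 0)
    if bad.any():
        genes = list(fc.index[bad])
        logger.error("zero-variance nonzero-mean differences: %s", genes[:5])
        raise ValueError(f"zero-variance differences with nonzero mean: {genes[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    df = n - 1
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    m = len(fc.index)
    out = pd.DataFrame(
        {
            "mean_log2_fc": mean,
            "fold_change_linear": 2.0 ** np.abs(mean),
            "var_fc": var,
            "t": t,
            "df": df,
            "p": p,
            "p_bonferroni": np.minimum(1.0, m * p),
        },
        index=fc.index,
    )
    out.index.name = "gene"
    return out


def classify_modest_changes(de: pd.DataFrame, fc_low: float = 1.2,
                            fc_high: float = 1.3, var_min: float = 0.02,
                            alpha: float = 0.05) -> set:
    """Significant genes with modest linear fold change and variable response.

    Keeps genes with Bonferroni-corrected p < alpha, |linear fold change|
    (2^|mean log2 fc|) within [fc_low, fc_high], and per-individual
    fold-change variance strictly above ``var_min``.
    """
    if not fc_low < fc_high:
        raise ValueError("fc_low must be < fc_high")
    lin = de["fold_change_linear"]
    keep = (de["p_bonferroni"] < alpha) & (lin >= fc_low) & (lin <= fc_high) & (
        de["var_fc"] > var_min)
    return set(de.index[keep])


def phenotype_correlation(changes: pd.DataFrame, phenotype: pd.Series,
                          r_min: float = 0.17,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each gene's expression change with a phenotype.

    ``changes`` is genes × individuals (e.g. from
    :func:`rewirenet.exprio.fold_change_matrix`); ``phenotype`` is indexed by
    individual.  A gene passes the filter when |r| > r_min and the two-sided
    p < alpha.
    """
    common = [i for i in changes.columns if i in phenotype.index]
    if len(common) < 10:
        raise ValueError(f"need >=10 individuals with both values, got {len(common)}")
    y = phenotype.reindex(common).to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    x = changes[common].to_numpy(dtype=float)
    n = len(common)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame(
        {"r": r, "p": p, "passes_filter": (np.abs(r) > r_min) & (p < alpha)},
        index=changes.index,
    )
    out.index.name = "gene"
    return out


def extreme_group_test(change: pd.Series, phenotype: pd.Series, k: int,
                       equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test of phenotype between extreme responders.

    Individuals are ranked by the gene's expression change; the phenotype of
    the top-k is compared with the bottom-k (equal-variance t by default,
    Welch via ``equal_var=False``).  Ties in the ranking are broken by
    individual-ID order (stable sort), which is logged when it happens.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    common = [i for i in change.index if i in phenotype.index]
    if 2 * k > len(common):
        raise ValueError(f"2k={2 * k} exceeds {len(common)} individuals")
    vals = change.reindex(common)
    if vals.duplicated().any():
        logger.info("ties in expression change broken by individual ID order")
    order = vals.to_frame("v").sort_values("v", kind="stable").index
    low, high = list(order[:k]), list(order[-k:])
    a = phenotype.reindex(high).to_numpy(dtype=float)
    b = phenotype.reindex(low).to_numpy(dtype=float)
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
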