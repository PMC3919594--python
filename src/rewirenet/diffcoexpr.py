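"""All-pairs coexpression and Fisher-homogeneity differential correlation.

Coexpression of two genes is their Pearson correlation across individuals
within one condition.  To find pairs whose coexpression *changes* between
conditions (or among time points), each condition's correlation is
Fisher-z-transformed, z = atanh(r) with variance ≈ 1/(n−3), and the k
condition-specific z-values are tested for homogeneity with the chi-square
statistic

    chi2 = sum_c w_c (z_c − z̄)²,   w_c = n_c − 3,   z̄ = sum w_c z_c / sum w_c,

on k−1 degrees of freedom; Bonferroni correction runs over the number of
gene pairs tested.  The test treats conditions as independent samples and
ignores the paired-individual dependence between them — a deliberate
simplification, documented as a caveat (it makes the test slightly
conservative when conditions are positively dependent).

Correlations are stored condensed (row-major upper triangle, the ordering of
``scipy.spatial.distance.squareform``) so the all-pairs table for thousands
of genes stays a flat float vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationSet",
    "num_unordered_pairs",
    "pairwise_correlations",
    "fisher_homogeneity",
    "differential_pairs",
    "variance_shift_check",
]


def num_unordered_pairs(n: int) -> int:
    """Number of unordered gene pairs among n genes, n(n−1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    return n * (n - 1) // 2


@dataclass
class CorrelationSet:
    """Condensed all-pairs Pearson correlations for one condition."""

    condition: str
    r: np.ndarray  # length n_genes*(n_genes-1)/2, squareform order
    n_samples: int
    genes: list

    def __post_init__(self) -> None:
        expect = num_unordered_pairs(len(self.genes))
        if len(self.r) != expect:
            raise ValueError(f"condensed length {len(self.r)} != {expect}")

    def pair_index(self, i: int, j: int) -> int:
        """Condensed index of the unordered pair (i, j)."""
        n = len(self.genes)
        if i == j:
            raise ValueError("no self-pairs")
        i, j = min(i, j), max(i, j)
        return n * i - i * (i + 1) // 2 + (j - i - 1)


def pairwise_correlations(matrix: pd.DataFrame, condition: str) -> CorrelationSet:
    """All-pairs Pearson correlation of a genes × samples matrix.

    Constant genes cannot be correlated and are dropped with a warning; at
    least 4 samples are required (the Fisher weight n−3 must be positive).
    """
    if matrix.shape[1] < 4:
        raise ValueError(f"need >=4 samples, got {matrix.shape[1]}")
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        dropped = list(matrix.index[sd == 0])
        logger.warning("dropping %d constant genes: %s", len(dropped), dropped[:5])
        matrix = matrix.loc[sd > 0]
        arr = matrix.to_numpy(dtype=float)
    corr = np.corrcoef(arr)
    iu = np.triu_indices(arr.shape[0], k=1)
    condensed = np.clip(corr[iu], -1.0, 1.0)
    return CorrelationSet(condition=condition, r=condensed,
                          n_samples=matrix.shape[1], genes=list(matrix.index))


def fisher_homogeneity(r_by_condition, n_by_condition):
    """Fisher's homogeneity test of k correlations sharing a common value.

    Accepts scalars (one pair) or aligned arrays (vectorized over pairs) per
    condition.  Returns (chi2, df, p) with df = k − 1.  |r| = 1 is rejected
    (infinite z); each condition needs n >= 4.
    """
    rs = [np.asarray(r, dtype=float) for r in r_by_condition]
    ns = [int(n) for n in n_by_condition]
    k = len(rs)
    if k < 2 or len(ns) != k:
        raise ValueError("need k >= 2 aligned (r, n) entries")
    if any(n < 4 for n in ns):
        raise ValueError("each condition needs n >= 4")
    for r in rs:
        if np.any(np.abs(r) >= 1.0):
            raise ValueError("|r| = 1 has infinite Fisher z; cannot test")
    z = np.stack([np.arctanh(r) for r in rs])  # (k, ...) stack
    w = np.array([n - 3 for n in ns], dtype=float)
    w_shaped = w.reshape((k,) + (1,) * (z.ndim - 1))
    zbar = (w_shaped * z).sum(axis=0) / w.sum()
    chi2 = (w_shaped * (z - zbar) ** 2).sum(axis=0)
    df = k - 1
    p = stats.chi2.sf(chi2, df)
    if np.ndim(chi2) == 0:
        return float(chi2), df, float(p)
    return chi2, df, p


def differential_pairs(corr_sets: list[CorrelationSet], alpha: float = 0.05,
                       m_override: int | None = None, full_table: bool = False):
    """Gene pairs whose correlation differs between conditions.

    Runs the Fisher homogeneity test on every pair, Bonferroni-corrects over
    m = number of pairs tested (or ``m_override``), and returns
    ``(pair_list, unique_genes, table)`` where ``table`` holds per-pair
    per-condition r, chi2, p and p_bonferroni for the significant pairs
    (all pairs when ``full_table``), sorted by descending chi2.
    """
    if len(corr_sets) < 2:
        raise ValueError("need >=2 correlation sets")
    genes = corr_sets[0].genes
    for cs in corr_sets[1:]:
        if cs.genes != genes:
            raise ValueError("correlation sets have mismatched gene order")
    chi2, df, p = fisher_homogeneity([cs.r for cs in corr_sets],
                                     [cs.n_samples for cs in corr_sets])
    m = m_override if m_override is not None else len(corr_sets[0].r)
    p_bonf = np.minimum(1.0, m * p)
    sig = p_bonf < alpha

    n = len(genes)
    iu = np.triu_indices(n, k=1)
    which = np.ones_like(sig, dtype=bool) if full_table else sig
    idx = np.flatnonzero(which)
    order = idx[np.argsort(chi2[idx])[::-1]]
    table = pd.DataFrame({
        "gene_a": [genes[iu[0][i]] for i in order],
        "gene_b": [genes[iu[1][i]] for i in order],
        **{f"r_{cs.condition}": cs.r[order] for cs in corr_sets},
        "chi2": chi2[order],
        "p": p[order],
        "p_bonferroni": p_bonf[order],
    })
    sig_idx = np.flatnonzero(sig)
    sig_order = sig_idx[np.argsort(chi2[sig_idx])[::-1]]
    pairs = [(genes[iu[0][i]], genes[iu[1][i]]) for i in sig_order]
    unique_genes = sorted({g for pair in pairs for g in pair})
    return pairs, unique_genes, table


def variance_shift_check(study: ExpressionStudy, genes, cond_a: str,
                         cond_b: str) -> tuple[float, pd.DataFrame]:
    """Mean |variance difference| between conditions for a gene set.

    A sanity check that called interaction changes are not an artifact of
    changed inter-individual variability: per gene, the sample variance of
    expression across individuals is computed in each condition and the mean
    absolute difference reported, with the per-gene table.
    """
    genes = list(genes)
    for g in genes:
        if g not in study.matrices[cond_a].index:
            raise ValueError(f"gene {g!r} not in study")
    va = study.matrices[cond_a].loc[genes].var(axis=1, ddof=1)
    vb = study.matrices[cond_b].loc[genes].var(axis=1, ddof=1)
    table = pd.DataFrame({f"var_{cond_a}": va, f"var_{cond_b}": vb,
                          "abs_diff": (vb - va).abs()})
    mean_abs = float(table["abs_diff"].mean()) if genes else 0.0
    return mean_abs, table
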