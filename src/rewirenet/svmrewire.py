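"""Per-gene SVR models and permutation ΔR² tests for interaction rewiring.

Each gene is modeled as a linear function of all other genes,
E(g_t) = sum_x w_tx · E(g_x) + b, learned by epsilon-insensitive linear
support-vector regression on *baseline* samples only (epsilon = 0.1, C = 1,
the remaining parameters at their defaults).  If the gene keeps its
relationships under stress, a model trained at baseline predicts stressed
expression about as well as held-out baseline expression; a drop in
performance, ΔR² = R²(baseline test) − R²(stressed), is the proxy for a
rewired gene.  R² is the *square of the Pearson correlation* between
predicted and actual expression (not 1 − SSE/SST — a sign-flipped perfect
predictor still scores 1; documented consequence of the definition).

Significance is empirical: baseline-test and stressed samples are pooled and
randomly reassigned to two groups of the original sizes; the permuted ΔR²
distribution gives a per-gene p-value with an add-one correction, and a
pooled-null FDR estimate across genes.  Every gene's training, testing and
z-normalization (training and evaluation sets normalized separately) follow
the same seeded split of individuals.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .synthgen import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "split_individuals",
    "zscore_normalize",
    "train_gene_model",
    "predict",
    "evaluate_r2",
    "permutation_test_delta_r2",
    "permutation_fdr",
    "rewired_gene_calls",
    "analyze_rewiring",
]


def split_individuals(individual_ids, train_fraction: float = 0.5,
                      seed: int = 0) -> tuple[list, list]:
    """Seeded random split of individuals into disjoint train/test sets.

    Train size = round(train_fraction · n); half-integers round up, so 131
    individuals at 0.5 give {66, 65} and 95 give {48, 47}.
    """
    ids = list(individual_ids)
    n = len(ids)
    if n < 6:
        raise ValueError(f"need >=6 individuals, got {n}")
    n_train = int(np.floor(n * train_fraction + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def zscore_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization to mean 0, sd 1 (ddof = 1) across samples.

    Constant genes become all-zero rows (logged).  Applied separately to each
    dataset (training, baseline-test, stressed) so no statistics leak across
    sets.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 samples to standardize")
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.info("%d constant genes set to zero rows", int(flat.sum()))
    out = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class GeneModel:
    """A trained linear SVR model for one target gene."""

    target: str
    weights: pd.Series  # indexed by predictor gene, excludes the target
    intercept: float
    training_samples: list
    epsilon: float
    C: float


def train_gene_model(target, train_matrix: pd.DataFrame, epsilon: float = 0.1,
                     C: float = 1.0) -> GeneModel:
    """Fit a linear epsilon-SVR predicting ``target`` from all other genes.

    ``train_matrix`` is an already-normalized genes × samples frame.  The
    exact dual solver (sklearn ``SVR(kernel="linear")``) is used, so fits are
    deterministic; the learned hyperplane is stored as explicit weights so
    evaluation never touches the training data again.
    """
    if target not in train_matrix.index:
        raise ValueError(f"target {target!r} not in matrix")
    X = train_matrix.drop(index=target).to_numpy(dtype=float).T
    y = train_matrix.loc[target].to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise ValueError(f"need >=10 training samples, got {X.shape[0]}")
    svr = SVR(kernel="linear", epsilon=epsilon, C=C)
    svr.fit(X, y)
    weights = pd.Series(np.asarray(svr.coef_).ravel(),
                        index=train_matrix.index.drop(target))
    return GeneModel(target=target, weights=weights,
                     intercept=float(np.asarray(svr.intercept_).ravel()[0]),
                     training_samples=list(train_matrix.columns),
                     epsilon=epsilon, C=C)


def predict(model: GeneModel, matrix: pd.DataFrame) -> np.ndarray:
    """Predicted target expression for each sample (column) of ``matrix``."""
    X = matrix.loc[model.weights.index].to_numpy(dtype=float)
    return model.weights.to_numpy() @ X + model.intercept


def evaluate_r2(model: GeneModel, matrix: pd.DataFrame) -> float:
    """R² = squared Pearson correlation of predicted vs actual target values.

    Constant predictions (or a constant actual vector) give R² = 0, logged.
    """
    pred = predict(model, matrix)
    actual = matrix.loc[model.target].to_numpy(dtype=float)
    return _corr_sq(pred, actual)


def _corr_sq(pred: np.ndarray, actual: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(actual) == 0:
        logger.info("constant vector in R² computation; returning 0")
        return 0.0
    r = np.corrcoef(pred, actual)[0, 1]
    return float(min(1.0, r * r))


def permutation_test_delta_r2(model: GeneModel, baseline_test: pd.DataFrame,
                              stressed: pd.DataFrame, n_perm: int = 1000,
                              seed: int = 0) -> tuple[float, float]:
    """Permutation test of the drop in R² from baseline-test to stressed.

    Observed ΔR² = R²(baseline_test) − R²(stressed).  Samples of both
    (separately normalized) sets are pooled; each permutation reassigns them
    to two groups of the original sizes and recomputes ΔR².
    p = (1 + #{ΔR²_perm ≥ ΔR²_obs}) / (1 + n_perm), so the smallest
    attainable p is 1/(n_perm+1).
    """
    obs, perms = _delta_r2_with_permutations(model, baseline_test, stressed,
                                             n_perm, seed)
    p = (1.0 + np.sum(perms >= obs)) / (1.0 + n_perm)
    return obs, float(p)


def _delta_r2_with_permutations(model, baseline_test, stressed, n_perm, seed):
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    if baseline_test.shape[1] == 0 or stressed.shape[1] == 0:
        raise ValueError("both evaluation sets must be nonempty")
    pred = np.concatenate([predict(model, baseline_test), predict(model, stressed)])
    actual = np.concatenate([
        baseline_test.loc[model.target].to_numpy(dtype=float),
        stressed.loc[model.target].to_numpy(dtype=float),
    ])
    n_b = baseline_test.shape[1]
    n_tot = len(actual)
    obs = _corr_sq(pred[:n_b], actual[:n_b]) - _corr_sq(pred[n_b:], actual[n_b:])
    rng = np.random.default_rng(seed)
    # one permutation per row; groups of the original sizes
    order = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    g1, g2 = order[:, :n_b], order[:, n_b:]
    perms = (_corr_sq_rows(pred[g1], actual[g1])
             - _corr_sq_rows(pred[g2], actual[g2]))
    return obs, perms


def _corr_sq_rows(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Row-wise squared Pearson correlation; 0 where either row is constant."""
    pc = pred - pred.mean(axis=1, keepdims=True)
    ac = actual - actual.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (ac**2).sum(axis=1))
    num = (pc * ac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (num / np.maximum(denom, 1e-300)) ** 2, 0.0)
    return np.minimum(1.0, r2)


def permutation_fdr(observed: np.ndarray, permuted: np.ndarray) -> np.ndarray:
    """Pooled-null FDR estimate for each gene's observed ΔR².

    For the threshold t at each observed value,
    FDR(t) = mean over permutations of #{genes with permuted ΔR² ≥ t}
             / max(1, #{genes with observed ΔR² ≥ t}),
    capped at 1 and monotonized q-value style (the estimate at a threshold is
    the minimum over all looser-or-equal thresholds' raw estimates, so FDR is
    non-decreasing as the threshold loosens).
    """
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    if permuted.ndim != 2 or permuted.shape[0] != observed.shape[0]:
        raise ValueError(
            f"permuted matrix shape {permuted.shape} does not match "
            f"{observed.shape[0]} genes")
    m, n_perm = permuted.shape
    order = np.argsort(observed)[::-1]  # thresholds descending
    thresholds = observed[order]
    perm_sorted = np.sort(permuted.ravel())
    # count permuted values >= t, averaged over permutations
    null_ge = (len(perm_sorted)
               - np.searchsorted(perm_sorted, thresholds, side="left")) / n_perm
    obs_ge = np.arange(1, m + 1)  # after sorting, #{observed >= t_k} = k (ties ok)
    raw = np.minimum(1.0, null_ge / np.maximum(1, obs_ge))
    q_desc = np.minimum.accumulate(raw[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = q_desc
    return fdr


def rewired_gene_calls(results: pd.DataFrame,
                       alpha: float = 0.01) -> tuple[set, float]:
    """Genes called rewired at permutation p < alpha, plus the FDR at the cut.

    The reported FDR is the largest per-gene FDR estimate among called genes
    (0.0 for an empty call set).
    """
    called = results.index[results["p_perm"] < alpha]
    fdr_at_cut = float(results.loc[called, "fdr"].max()) if len(called) else 0.0
    return set(called), fdr_at_cut


def analyze_rewiring(study: ExpressionStudy, baseline_label: str,
                     stress_label: str, train_fraction: float = 0.5,
                     epsilon: float = 0.1, C: float = 1.0, n_perm: int = 1000,
                     seed: int = 0, genes=None) -> pd.DataFrame:
    """Run the full SVM-rewiring arm for every gene (or a subset).

    Individuals present at baseline are split once into train/test; stressed
    evaluation uses ALL stressed samples (including those of training
    individuals), mirroring the study design this emulates — the induced
    optimism affects every gene equally.  Training, baseline-test and
    stressed matrices are z-normalized separately.  Returns a DataFrame with
    r2_baseline, r2_stressed, delta_r2, p_perm and fdr per gene; results are
    independent of gene evaluation order (each gene draws its permutation
    stream from a per-gene spawn of ``seed``).
    """
    base_ind = list(study.individuals(baseline_label))
    train_ids, test_ids = split_individuals(base_ind, train_fraction, seed)
    ind_to_col = {v: k for k, v in study.individuals(baseline_label).items()}
    base_mat = study.matrices[baseline_label]
    train_mat = zscore_normalize(base_mat[[ind_to_col[i] for i in train_ids]])
    test_mat = zscore_normalize(base_mat[[ind_to_col[i] for i in test_ids]])
    stress_mat = zscore_normalize(study.matrices[stress_label])

    targets = list(genes) if genes is not None else study.gene_ids
    rows = []
    perm_rows = []
    for target in targets:
        model = train_gene_model(target, train_mat, epsilon=epsilon, C=C)
        r2_b = evaluate_r2(model, test_mat)
        r2_s = evaluate_r2(model, stress_mat)
        # per-gene stream keyed by the gene ID so results do not depend on
        # evaluation order or on which other genes are analyzed
        gene_key = int.from_bytes(
            hashlib.sha256(str(target).encode()).digest()[:4], "big")
        obs, perms = _delta_r2_with_permutations(
            model, test_mat, stress_mat, n_perm,
            np.random.default_rng([seed, 4, gene_key]))
        p = (1.0 + np.sum(perms >= obs)) / (1.0 + n_perm)
        rows.append((target, r2_b, r2_s, obs, p))
        perm_rows.append(perms)
    out = pd.DataFrame(rows, columns=["gene", "r2_baseline", "r2_stressed",
                                      "delta_r2", "p_perm"]).set_index("gene")
    out["fdr"] = permutation_fdr(out["delta_r2"].to_numpy(),
                                 np.asarray(perm_rows))
    return out
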