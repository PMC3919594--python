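"""Per-gene SVR models, the ΔR² permutation test and the pooled-null FDR."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rewirenet import svmrewire
from rewirenet.svmrewire import (analyze_rewiring, evaluate_r2, permutation_fdr,
                                 permutation_test_delta_r2, predict,
                                 rewired_gene_calls, split_individuals,
                                 train_gene_model, zscore_normalize)
from rewirenet.synthgen import generate_module_switch_study


@pytest.mark.parametrize("n,expected", [(131, (66, 65)), (95, (48, 47))])
def test_split_sizes_reproduce_study_design(n, expected):
    train, test = split_individuals([f"i{k}" for k in range(n)], 0.5, seed=1)
    assert (len(train), len(test)) == expected
    assert set(train).isdisjoint(test)
    assert len(set(train) | set(test)) == n


def test_split_determinism_and_guards():
    ids = [f"i{k}" for k in range(20)]
    assert split_individuals(ids, 0.5, 7) == split_individuals(ids, 0.5, 7)
    assert split_individuals(ids, 0.5, 7) != split_individuals(ids, 0.5, 8)
    with pytest.raises(ValueError):
        split_individuals(ids[:4], 0.5, 1)
    with pytest.raises(ValueError):
        split_individuals(ids, 0.001, 1)


def test_zscore_normalize(rng):
    mat = pd.DataFrame(rng.normal(5, 3, size=(10, 40)))
    out = zscore_normalize(mat)
    assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)
    # affine transform of the input changes nothing
    out2 = zscore_normalize(mat * 7.5 - 3.0)
    assert np.allclose(out.to_numpy(), out2.to_numpy(), atol=1e-9)
    flat = mat.copy()
    flat.iloc[3] = 2.0
    assert np.allclose(zscore_normalize(flat).iloc[3], 0.0)


def _toy_matrices(rng, n_genes=10, n_train=60, n_test=40, copy_of=1):
    """Target g0 is an exact copy of predictor g<copy_of>."""
    train = rng.normal(size=(n_genes, n_train))
    test = rng.normal(size=(n_genes, n_test))
    train[0], test[0] = train[copy_of], test[copy_of]
    genes = [f"g{i}" for i in range(n_genes)]
    tr = zscore_normalize(pd.DataFrame(train, index=genes))
    te = zscore_normalize(pd.DataFrame(test, index=genes))
    return tr, te


def test_realizable_target_high_r2(rng):
    train, test = _toy_matrices(rng)
    model = train_gene_model("g0", train)
    assert evaluate_r2(model, test) >= 0.99
    assert "g0" not in model.weights.index


def test_independent_target_low_r2(rng):
    train = zscore_normalize(pd.DataFrame(rng.normal(size=(201, 66)),
                                          index=[f"g{i}" for i in range(201)]))
    test = zscore_normalize(pd.DataFrame(rng.normal(size=(201, 65)),
                                         index=train.index))
    model = train_gene_model("g0", train)
    assert evaluate_r2(model, test) < 0.2


def test_signal_fraction_recovered(rng):
    """Target = 0.5(g1+g2) + noise: held-out R² near the analytic signal share."""
    n = 500
    genes = [f"g{i}" for i in range(21)]
    X = rng.normal(size=(21, n))
    noise_sd = 0.5
    X[0] = 0.5 * (X[1] + X[2]) + rng.normal(scale=noise_sd, size=n)
    signal_frac = 0.5 / (0.5 + noise_sd**2)  # var(signal)=0.5
    df = pd.DataFrame(X, index=genes)
    train = zscore_normalize(df.iloc[:, :250])
    test = zscore_normalize(df.iloc[:, 250:])
    model = train_gene_model("g0", train)
    assert evaluate_r2(model, test) == pytest.approx(signal_frac, abs=0.1)


def test_evaluate_r2_definition(rng):
    train, test = _toy_matrices(rng)
    model = train_gene_model("g0", train)
    # correlation-squared: a sign-flipped perfect predictor still scores 1
    flipped = model
    flipped.weights = -model.weights
    flipped.intercept = -model.intercept
    assert evaluate_r2(flipped, test) >= 0.99
    # hand-computed Pearson^2 on 5 samples
    pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    actual = np.array([1.1, 1.9, 3.3, 3.6, 5.2])
    r_hand = np.corrcoef(pred, actual)[0, 1] ** 2
    assert svmrewire._corr_sq(pred, actual) == pytest.approx(r_hand, abs=1e-12)
    assert svmrewire._corr_sq(np.ones(5), actual) == 0.0


def test_train_test_separation(rng):
    train, test = _toy_matrices(rng)
    model1 = train_gene_model("g0", train)
    test2 = test + rng.normal(size=test.shape)  # corrupt the test set
    model2 = train_gene_model("g0", train)
    h = lambda m: hashlib.sha256(m.weights.to_numpy().tobytes()).hexdigest()
    assert h(model1) == h(model2)


def test_permutation_add_one_rule():
    """An observed ΔR² above every permuted value gives p = 1/(n_perm+1)."""
    study, _ = generate_module_switch_study(n_genes=60, n_individuals=100,
                                            n_switch=1, module_size=15, seed=3)
    res = analyze_rewiring(study, "baseline", "stress", n_perm=1000, seed=3,
                           genes=["g0000"])
    assert res["p_perm"].iloc[0] == pytest.approx(1 / 1001)


def test_permutation_null_p_uniform():
    """With no rewiring, the permutation p-value is uniform over studies."""
    ps = []
    for seed in range(100):
        study, _ = generate_module_switch_study(
            n_genes=40, n_individuals=60, n_switch=1, module_size=10,
            switch=False, seed=seed)
        res = analyze_rewiring(study, "baseline", "stress", n_perm=200,
                               seed=seed, genes=["g0000"])
        ps.append(res["p_perm"].iloc[0])
    _, p = stats.kstest(ps, "uniform")
    assert p > 0.01


def test_planted_rewiring_detected():
    hits = 0
    for seed in range(20):
        study, _ = generate_module_switch_study(n_genes=100, n_individuals=100,
                                                n_switch=1, seed=seed)
        res = analyze_rewiring(study, "baseline", "stress", n_perm=200,
                               seed=seed, genes=["g0000"])
        hits += res["p_perm"].iloc[0] < 0.01
    assert hits >= 18


def test_permutation_fdr_extremes(rng):
    obs = np.array([1.0, 0.9, 0.8])
    permuted = rng.normal(scale=0.01, size=(3, 200))
    fdr = permutation_fdr(obs, permuted)
    assert (fdr < 0.02).all()
    # observed drawn from the null itself: FDR near 1 at the median threshold
    null_obs = rng.normal(size=400)
    null_perm = rng.normal(size=(400, 50))
    fdr = permutation_fdr(null_obs, null_perm)
    med = np.argsort(null_obs)[200]
    assert fdr[med] > 0.7
    assert (np.diff(fdr[np.argsort(null_obs)[::-1]]) >= -1e-12).all()  # monotone
    with pytest.raises(ValueError):
        permutation_fdr(null_obs, null_perm[:100])


def test_rewired_gene_calls_and_order_independence():
    study, part = generate_module_switch_study(n_genes=60, n_individuals=100,
                                               n_switch=2, module_size=20,
                                               seed=6)
    subset = ["g0000", "g0001", "g0010", "g0050"]
    res1 = analyze_rewiring(study, "baseline", "stress", n_perm=200, seed=6,
                            genes=subset)
    res2 = analyze_rewiring(study, "baseline", "stress", n_perm=200, seed=6,
                            genes=subset[::-1])
    pd.testing.assert_frame_equal(res1.sort_index(), res2.sort_index())
    called, fdr_at_cut = rewired_gene_calls(res1, alpha=0.01)
    assert called >= set(part["switch"])
    empty, fdr0 = rewired_gene_calls(res1, alpha=0.0)
    assert empty == set() and fdr0 == 0.0


def test_planted_rank_recovery():
    """Planted rewired genes dominate the p-value ranking."""
    study, part = generate_module_switch_study(n_genes=100, n_individuals=100,
                                               n_switch=10, module_size=25,
                                               seed=11)
    res = analyze_rewiring(study, "baseline", "stress", n_perm=200, seed=11)
    ranks = res["p_perm"].rank(method="average")
    planted_ranks = ranks.loc[part["switch"]]
    assert planted_ranks.median() <= 15
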