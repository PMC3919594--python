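"""I/O round-trips and the preprocessing chain (collapse, filter, scale)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from rewirenet import exprio
from rewirenet.synthgen import SyntheticConfig, generate_study

from conftest import build_study


def test_write_read_roundtrip(tmp_path):
    cfg = SyntheticConfig(n_genes=12, n_individuals=8, seed=1)
    study, _ = generate_study(cfg)
    exprio.write_study(study, tmp_path)
    back = exprio.read_study(
        {c: tmp_path / f"expression_{c}.tsv" for c in study.conditions},
        tmp_path / "samples.tsv")
    for c in study.conditions:
        pd.testing.assert_frame_equal(back.matrices[c], study.matrices[c])


def test_missing_sample_named_in_error(tmp_path):
    cfg = SyntheticConfig(n_genes=5, n_individuals=4, seed=2)
    study, _ = generate_study(cfg)
    exprio.write_study(study, tmp_path)
    meta = pd.read_csv(tmp_path / "samples.tsv", sep="\t")
    meta[meta["sample_id"] != "baseline_ind002"].to_csv(
        tmp_path / "samples.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="baseline_ind002"):
        exprio.read_study(
            {c: tmp_path / f"expression_{c}.tsv" for c in study.conditions},
            tmp_path / "samples.tsv")


def test_duplicated_gene_ids_error(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
    with pytest.raises(ValueError, match="duplicated"):
        exprio.read_matrix_tsv(path)


def test_pairing_reconstructed_for_shared_individuals():
    base = np.zeros((3, 5))
    stress = np.zeros((3, 4))
    study = build_study(base, stress,
                       base_inds=[f"i{k}" for k in range(5)],
                       stress_inds=["i2", "i3", "i4", "i9"])
    assert study.paired_individuals("baseline", "stress") == ["i2", "i3", "i4"]


# ---------------------------------------------------------------- collapsing

def _pmap(probes):
    return pd.DataFrame({"probeset_id": list(probes),
                         "gene_symbol": [probes[p] for p in probes]}
                        ).set_index("probeset_id")


def test_collapse_single_probeset_identity():
    mat = pd.DataFrame(np.arange(6).reshape(3, 2),
                       index=["a_at", "b_at", "c_at"], columns=["s1", "s2"])
    pmap = _pmap({"a_at": "A", "b_at": "B", "c_at": "C"})
    out = exprio.collapse_probesets(mat, pmap, seed=0)
    assert sorted(out.index) == ["A", "B", "C"]
    assert out.loc["B"].tolist() == mat.loc["b_at"].tolist()


def test_collapse_excludes_x_at():
    mat = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                       index=["a_at", "b_x_at"], columns=["s1", "s2"])
    pmap = _pmap({"a_at": "G", "b_x_at": "G"})
    for seed in range(10):
        out = exprio.collapse_probesets(mat, pmap, seed=seed)
        assert out.loc["G"].tolist() == [1.0, 2.0]


def test_collapse_gene_with_only_x_at_dropped():
    mat = pd.DataFrame([[1.0], [2.0]], index=["a_x_at", "b_at"], columns=["s"])
    pmap = _pmap({"a_x_at": "LOST", "b_at": "KEPT"})
    out = exprio.collapse_probesets(mat, pmap, seed=0)
    assert list(out.index) == ["KEPT"]


def test_collapse_uniform_choice_over_seeds():
    """Three eligible probesets are each picked about 1/3 of the time."""
    mat = pd.DataFrame(np.eye(3), index=["p1_at", "p2_at", "p3_at"],
                       columns=["s1", "s2", "s3"])
    pmap = _pmap({"p1_at": "G", "p2_at": "G", "p3_at": "G"})
    counts = {"p1_at": 0, "p2_at": 0, "p3_at": 0}
    for seed in range(300):
        out = exprio.collapse_probesets(mat, pmap, seed=seed)
        chosen = np.flatnonzero(out.loc["G"].to_numpy())[0]
        counts[f"p{chosen + 1}_at"] += 1
    chi2, p = stats.chisquare(list(counts.values()))
    assert p > 0.01


# ------------------------------------------------------------ present filter

def test_present_filter_in_either_condition():
    calls = {
        "baseline": pd.DataFrame([["P"] * 79 + ["A"] * 21,
                                  ["P"] * 79 + ["A"] * 21], index=["gA", "gB"]),
        "stress": pd.DataFrame([["P"] * 81 + ["A"] * 19,
                                ["P"] * 79 + ["A"] * 21], index=["gA", "gB"]),
    }
    kept = exprio.present_filter(calls, threshold=0.8)
    assert kept == ["gA"]  # 81% in stress suffices; gB fails both


def test_present_filter_all_present_and_monotone():
    rng = np.random.default_rng(0)
    arr = np.where(rng.random((30, 40)) < 0.85, "P", "A")
    calls = {"c1": pd.DataFrame(arr), "c2": pd.DataFrame(arr[:, ::-1])}
    assert len(exprio.present_filter(
        {"c1": pd.DataFrame(np.full((5, 5), "P"))}, 0.8)) == 5
    prev = None
    for thr in (0.5, 0.7, 0.9, 1.0):
        kept = set(exprio.present_filter(calls, thr))
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_present_filter_errors():
    with pytest.raises(ValueError):
        exprio.present_filter({}, 0.8)
    with pytest.raises(ValueError):
        exprio.present_filter({"c": pd.DataFrame([["P"]])}, 0.0)


# ------------------------------------------------------------- scale and log

def test_scale_constant_sample_hits_target():
    raw = pd.DataFrame(np.full((50, 3), 250.0))
    out = exprio.scale_and_log(raw, target=500.0)
    assert np.allclose(out.to_numpy(), np.log2(500.0))


def test_scale_invariance_and_idempotence(rng):
    raw = pd.DataFrame(rng.gamma(2.0, 200.0, size=(200, 4)))
    out1 = exprio.scale_and_log(raw)
    out2 = exprio.scale_and_log(2.0 * raw)
    assert np.allclose(out1.to_numpy(), out2.to_numpy())
    # a sample already at the target is unchanged up to the log transform
    arr = raw.to_numpy()
    scaled = arr * (500.0 / np.array([stats.trim_mean(arr[:, j], 0.02)
                                      for j in range(4)]))
    again = exprio.scale_and_log(pd.DataFrame(scaled))
    assert np.allclose(again.to_numpy(),
                       np.log2(np.clip(scaled, 1.0, None)), atol=1e-9)


def test_scale_rejects_bad_input():
    with pytest.raises(ValueError):
        exprio.scale_and_log(pd.DataFrame([[0.0], [0.0]]))
    with pytest.raises(ValueError):
        exprio.scale_and_log(pd.DataFrame([[-1.0], [2.0]]))


# -------------------------------------------------------- fold change matrix

def test_fold_change_matrix_values_and_pairing():
    base = np.full((2, 5), 8.0)
    stress = np.full((2, 3), 9.0)
    study = build_study(base, stress,
                       base_inds=[f"i{k}" for k in range(5)],
                       stress_inds=["i0", "i1", "i2"])
    fc = exprio.fold_change_matrix(study, "baseline", "stress")
    assert fc.shape == (2, 3)
    assert np.allclose(fc.to_numpy(), 1.0)  # one log2 unit = 2-fold


def test_fold_change_zero_when_identical():
    arr = np.random.default_rng(1).normal(8, 1, (4, 6))
    study = build_study(arr, arr)
    fc = exprio.fold_change_matrix(study, "baseline", "stress")
    assert np.allclose(fc.to_numpy(), 0.0)


def test_fold_change_requires_pairs():
    study = build_study(np.zeros((2, 3)), np.zeros((2, 3)),
                        base_inds=["a", "b", "c"], stress_inds=["x", "y", "z"])
    with pytest.raises(ValueError):
        exprio.fold_change_matrix(study, "baseline", "stress")


@given(st.integers(2, 30))
def test_collapse_output_unique_genes(n):
    probes = {f"p{i}_at": f"G{i % max(2, n // 2)}" for i in range(n)}
    mat = pd.DataFrame(np.ones((n, 2)), index=list(probes), columns=["s1", "s2"])
    out = exprio.collapse_probesets(mat, _pmap(probes), seed=1)
    assert out.index.is_unique
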