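"""End-to-end orchestration, set-overlap statistics and cross-stress comparison.

``run_pipeline`` executes the full analysis on one study — preprocessing,
paired differential expression, Fisher-homogeneity differential coexpression,
network topology with degree-preserving nulls, and the SVM-rewiring arm —
from a single YAML/JSON config with one global seed, writing plain TSV/JSON
results that are byte-reproducible from config + seed.

The remaining operations implement the comparative statistics: genes that
change interactions *without* changing expression, hypergeometric overlap of
gene sets against the expressed-gene universe, annotation-sharing enrichment
of coexpressed pairs against degree-preserving random pairs, and the
two-stress specificity comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import diffcoexpr, diffexpr, exprio, nettopo, svmrewire, synthgen

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "interaction_without_expression_change",
    "overlap_hypergeometric",
    "annotation_sharing_test",
    "compare_stresses",
    "read_gmt",
    "StudyComparison",
]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every analysis stage on one study; write results under ``out_dir``.

    ``config`` is a dict or a YAML/JSON file with blocks
    ``{synthgen | input, preprocess, de, diffcoexpr, topology, svm}`` and a
    global ``seed``.  Any stage failure aborts with the stage name and cause.
    Result files (TSV/JSON) are deterministic given config + seed; stage
    timings go to ``run.log`` only.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log_lines = [f"config_hash={_config_hash(config)}", f"seed={seed}"]
    results: dict = {"config_hash": _config_hash(config), "seed": seed}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log_lines.append(f"stage={name} seconds={time.perf_counter() - t0:.2f}")
        return value

    # --- input -----------------------------------------------------------
    def load():
        if "synthgen" in config:
            cfg = synthgen.config_from_dict({**config["synthgen"], "seed": seed})
            study, truth, calls = synthgen.generate_all(cfg)
            return study, calls
        inp = config["input"]
        study = exprio.read_study(inp["expression"], inp["metadata"])
        calls = None
        if "calls" in inp:
            calls = {c: pd.read_csv(p, sep="\t", index_col=0)
                     for c, p in inp["calls"].items()}
        return study, calls

    study, calls = stage("input", load)
    baseline = config.get("baseline", synthgen.BASELINE)
    stress = config.get("stress", synthgen.STRESS)

    # --- preprocess: present-call filter ---------------------------------
    pre = config.get("preprocess", {})
    if calls is not None and pre.get("present_threshold"):
        keep = stage("present_filter", lambda: exprio.present_filter(
            calls, float(pre["present_threshold"])))
        study = synthgen.ExpressionStudy(
            matrices={c: m.loc[keep] for c, m in study.matrices.items()},
            samples=study.samples)
        log_lines.append(f"present_filter kept {len(keep)} genes")
    results["n_genes"] = len(study.gene_ids)
    results["n_individuals"] = len(study.paired_individuals(baseline, stress))

    # --- differential expression -----------------------------------------
    de_cfg = config.get("de", {})
    de = stage("de", lambda: diffexpr.paired_t_tests(study, baseline, stress))
    de.to_csv(out / "de.tsv", sep="\t")
    de_alpha = float(de_cfg.get("alpha", 0.05))
    de_genes = set(de.index[de["p_bonferroni"] < de_alpha])
    results["n_de_genes"] = len(de_genes)
    log_lines.append(f"de: {len(de_genes)}/{len(de)} genes at Pc<{de_alpha}")

    # --- differential coexpression ---------------------------------------
    dc_cfg = config.get("diffcoexpr", {})
    corr_sets = stage("correlations", lambda: [
        diffcoexpr.pairwise_correlations(study.matrices[c], c)
        for c in (baseline, stress)])
    pairs, pair_genes, table = stage("diffcoexpr", lambda: (
        diffcoexpr.differential_pairs(corr_sets,
                                      alpha=float(dc_cfg.get("alpha", 0.05)))))
    table.to_csv(out / "diffcoexpr_pairs.tsv", sep="\t", index=False)
    results["n_diff_pairs"] = len(pairs)
    results["n_diff_pair_genes"] = len(pair_genes)

    # --- network topology -------------------------------------------------
    topo_cfg = config.get("topology", {})
    tau = float(topo_cfg.get("tau", 0.6))
    n_nulls = int(topo_cfg.get("n_nulls", 3))

    def topo():
        summary = {}
        for cs in corr_sets:
            net = nettopo.threshold_network(cs, tau)
            s = nettopo.summarize_topology(net)
            null_cc = [
                nettopo.clustering_coefficient(
                    nettopo.rewire_random(net, seed=seed + 1000 + i))
                for i in range(n_nulls)
            ] if net.number_of_edges() >= 2 else []
            summary[cs.condition] = {
                "n_nodes": s.n_nodes, "n_edges": s.n_edges,
                "mean_clustering": s.mean_clustering,
                "gamma": s.gamma, "scale_free_r2": s.scale_free_r2,
                "null_mean_clustering": (float(np.mean(null_cc))
                                         if null_cc else None),
            }
        nets = [nettopo.threshold_network(cs, tau) for cs in corr_sets]
        k = min(int(topo_cfg.get("hub_k", 100)), nets[0].number_of_nodes())
        summary["hub_overlap"] = nettopo.hub_overlap(nets[0], nets[1], k)
        return summary

    topo_summary = stage("topology", topo)
    (out / "topology.json").write_text(json.dumps(topo_summary, indent=1))
    results["hub_overlap"] = topo_summary["hub_overlap"]

    # --- SVM rewiring ------------------------------------------------------
    svm_cfg = config.get("svm", {})
    genes = study.gene_ids[: int(svm_cfg["genes"])] if "genes" in svm_cfg else None
    svm = stage("svm", lambda: svmrewire.analyze_rewiring(
        study, baseline, stress,
        train_fraction=float(svm_cfg.get("train_fraction", 0.5)),
        epsilon=float(svm_cfg.get("epsilon", 0.1)),
        C=float(svm_cfg.get("C", 1.0)),
        n_perm=int(svm_cfg.get("n_perm", 1000)),
        seed=seed, genes=genes))
    svm.to_csv(out / "svm.tsv", sep="\t")
    svm_alpha = float(svm_cfg.get("alpha", 0.01))
    svm_calls, fdr_at_cut = svmrewire.rewired_gene_calls(svm, alpha=svm_alpha)
    results["n_svm_rewired"] = len(svm_calls)
    results["svm_fdr_at_cut"] = fdr_at_cut
    results["n_interaction_without_expression_change"] = len(
        interaction_without_expression_change(svm_calls, de, alpha_de=de_alpha))

    (out / "summary.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def interaction_without_expression_change(svm_calls: set, de: pd.DataFrame,
                                          alpha_de: float = 0.05) -> set:
    """Rewired genes whose mRNA level did NOT change (Bonferroni p >= alpha)."""
    return {g for g in svm_calls if g in de.index
            and de.at[g, "p_bonferroni"] >= alpha_de}


def overlap_hypergeometric(set_a: set, set_b: set,
                           universe: set) -> tuple[int, float, float]:
    """Overlap of two gene sets against a finite universe.

    Returns (observed overlap, expected overlap K·n/N, upper-tail p
    P(X >= observed) for X ~ Hypergeometric(N, K, n)).
    """
    universe = set(universe)
    if not set(set_a) <= universe or not set(set_b) <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    obs = len(set(set_a) & set(set_b))
    expected = K * n / N if N else 0.0
    p = float(stats.hypergeom.sf(obs - 1, N, K, n))
    return obs, expected, p


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read GMT annotation sets: term <tab> description <tab> genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(fields[2:])
    if not sets:
        raise ValueError("empty GMT file")
    return sets


def annotation_sharing_test(pairs, null_pairs,
                            annotations: dict[str, set]) -> tuple[float, float, float]:
    """Do coexpressed pairs share annotations more often than random pairs?

    A pair "shares" when both genes carry at least one common term.  The
    observed sharing fraction is compared with the fraction among
    degree-preserving random pairs by a two-proportion z-test; when any count
    is below 5, Fisher's exact test is used instead.
    """
    if not any(annotations.values()):
        raise ValueError("no annotated genes")
    term_of: dict[str, set] = {}
    for term, members in annotations.items():
        for g in members:
            term_of.setdefault(g, set()).add(term)

    def share_count(pair_list):
        return sum(
            1 for a, b in pair_list
            if term_of.get(a, set()) & term_of.get(b, set())
        )

    pairs, null_pairs = list(pairs), list(null_pairs)
    if not pairs or not null_pairs:
        raise ValueError("both pair lists must be nonempty")
    s_obs, s_null = share_count(pairs), share_count(null_pairs)
    f_obs, f_null = s_obs / len(pairs), s_null / len(null_pairs)
    counts = [s_obs, len(pairs) - s_obs, s_null, len(null_pairs) - s_null]
    if min(counts) < 5:
        _, p = stats.fisher_exact([[s_obs, len(pairs) - s_obs],
                                   [s_null, len(null_pairs) - s_null]])
    else:
        from statsmodels.stats.proportion import proportions_ztest
        _, p = proportions_ztest([s_obs, s_null],
                                 [len(pairs), len(null_pairs)])
    if f_obs == f_null:
        p = 1.0
    return f_obs, f_null, float(p)


@dataclass
class StudyComparison:
    """Per-arm sharing of significant genes between two stress studies."""

    shared_universe: set
    arms: dict  # arm -> {set_a, set_b, intersection, union, frac_*}


def compare_stresses(results_a: dict, results_b: dict) -> StudyComparison:
    """Compare two runs' significant gene sets arm by arm.

    Each input maps arm name (e.g. ``expression``, ``coexpression_pairs``,
    ``svm``) to a gene set, plus a ``universe`` key.  Sets are intersected
    with the shared universe (intersection of the two runs' universes);
    per-arm sharing fractions are reported over that universe.  Symmetric in
    its arguments.
    """
    universe = set(results_a["universe"]) & set(results_b["universe"])
    if not universe:
        raise ValueError("empty shared gene universe")
    arms = {}
    for arm in sorted((set(results_a) | set(results_b)) - {"universe"}):
        sa = set(results_a.get(arm, set())) & universe
        sb = set(results_b.get(arm, set())) & universe
        inter, union = sa & sb, sa | sb
        arms[arm] = {
            "set_a": sa, "set_b": sb,
            "intersection": inter, "union": union,
            "n_shared": len(inter),
            "frac_of_universe_shared": len(inter) / len(universe),
            "frac_a_shared": len(inter) / len(sa) if sa else 0.0,
            "frac_b_shared": len(inter) / len(sb) if sb else 0.0,
        }
    return StudyComparison(shared_universe=universe, arms=arms)
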