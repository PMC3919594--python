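"""Synthetic paired two-condition expression studies with planted truth.

The generator emulates the design of a paired stress-response study on
cultured cells from ~100 unrelated individuals: every individual is assayed
once at baseline and once under stress, expression is on the log2 scale, and
three kinds of structure can be planted with known parameters:

* differentially expressed genes (an additive log2 shift under stress),
* "rewired" gene pairs whose Pearson correlation changes between conditions,
* genes whose stress-induced expression change drives a quantitative
  phenotype (a caspase-activity-like cell-death readout).

The generative model for gene ``g``, individual ``i``, condition ``c`` is

    x_{gic} = mu_g + a_i + lambda * F_{b(g),i,c} + beta_{gc} * P_{p(g),i,c}
              + delta_g * 1[c = stress] + eps_{gic}

with a shared individual effect ``a_i ~ N(0, individual_effect_sd^2)``
(identical in both conditions — the paired design), per-condition standard
normal block factors ``F`` giving background coexpression blocks, a pair
factor ``P`` shared by the two genes of a planted pair with loadings solved
so the model-implied correlation equals the requested value exactly, and iid
noise ``eps ~ N(0, noise_sd^2)``.  Genes in a planted pair are excluded from
blocks so the implied pair correlation stays analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "ExpressionStudy",
    "SyntheticTruth",
    "generate_study",
    "generate_detection_calls",
    "generate_phenotype",
    "generate_all",
    "generate_module_switch_study",
]

BASELINE = "baseline"
STRESS = "stress"


class InfeasibleLoadingError(ValueError):
    """Requested pair correlation cannot be realized by the factor model."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic paired two-condition study.

    Defaults mirror the scale of the motivating study design: ~100 paired
    individuals, thousands of genes, block-correlated background, modest
    fold changes (1.2–2x, i.e. 0.26–1.0 on the log2 scale).
    """

    n_genes: int = 2000
    n_individuals: int = 100
    n_blocks: int = 20
    block_loading: float = 0.5
    rewired_pairs: tuple[tuple[int, int, float, float], ...] = ()
    de_genes: tuple[tuple[int, float], ...] = ()
    phenotype_genes: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 0.5
    individual_effect_sd: float = 0.2
    present_fraction: float = 0.95
    low_presence_genes: tuple[int, ...] = ()
    low_presence_fraction: float = 0.5
    phenotype_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_individuals < 1:
            raise ValueError("n_genes and n_individuals must be positive")
        if self.block_loading < 0.0:  # loading is in log2 units
            raise ValueError("block_loading must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.individual_effect_sd < 0:
            raise ValueError("individual_effect_sd must be nonnegative")
        if not 0.0 <= self.present_fraction <= 1.0:
            raise ValueError("present_fraction must be in [0, 1]")
        seen: set[int] = set()
        for gi, gj, rb, rs in self.rewired_pairs:
            for g in (gi, gj):
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"rewired gene index {g} out of range")
                if g in seen:
                    raise ValueError(f"gene {g} appears in two rewired pairs")
                seen.add(g)
            if gi == gj:
                raise ValueError("a rewired pair must join two distinct genes")
            for r in (rb, rs):
                if abs(r) > 0.99:
                    raise ValueError(f"planted |r| must be <= 0.99, got {r}")
        for g, _ in self.de_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"DE gene index {g} out of range")
        for g, _ in self.phenotype_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"phenotype gene index {g} out of range")


@dataclass
class ExpressionStudy:
    """Per-condition log2 expression matrices plus sample→individual pairing.

    ``matrices`` maps a condition label to a genes × samples DataFrame whose
    index is ``gene_ids`` (identical across conditions).  ``samples`` holds
    one row per sample (index = sample_id) with columns ``individual_id`` and
    ``condition``; an individual appears at most once per condition.
    """

    matrices: dict[str, pd.DataFrame]
    samples: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return list(self.matrices)

    @property
    def gene_ids(self) -> list[str]:
        return list(next(iter(self.matrices.values())).index)

    def validate(self) -> None:
        genes = None
        for cond, mat in self.matrices.items():
            if genes is None:
                genes = list(mat.index)
            elif list(mat.index) != genes:
                raise ValueError(f"gene order differs in condition {cond!r}")
            if not np.isfinite(mat.to_numpy()).all():
                raise ValueError(f"non-finite expression values in {cond!r}")
            meta = self.samples[self.samples["condition"] == cond]
            missing = set(mat.columns) - set(meta.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            if meta["individual_id"].duplicated().any():
                dup = meta["individual_id"][meta["individual_id"].duplicated()].iloc[0]
                raise ValueError(f"individual {dup!r} appears twice in {cond!r}")

    def individuals(self, condition: str) -> pd.Series:
        """sample_id → individual_id for one condition, in matrix column order."""
        meta = self.samples[self.samples["condition"] == condition]
        return meta["individual_id"].reindex(self.matrices[condition].columns)

    def paired_individuals(self, cond_a: str, cond_b: str) -> list[str]:
        ia = set(self.individuals(cond_a))
        ib = set(self.individuals(cond_b))
        shared = ia & ib
        # stable order: as they appear in cond_a
        return [i for i in self.individuals(cond_a) if i in shared]


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated study, for verification."""

    de_genes: tuple[tuple[int, float], ...]
    rewired_pairs: tuple[tuple[int, int, float, float], ...]
    phenotype_genes: tuple[tuple[int, float], ...]
    phenotype: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": [list(t) for t in self.de_genes],
            "rewired_pairs": [list(t) for t in self.rewired_pairs],
            "phenotype_genes": [list(t) for t in self.phenotype_genes],
            "phenotype": None
            if self.phenotype is None
            else {str(k): float(v) for k, v in self.phenotype.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _pair_loading(r: float, noise_sd: float, individual_effect_sd: float,
                  pair: tuple[int, int]) -> tuple[float, float]:
    """Loading magnitude and sign of the loading product realizing corr = r.

    With shared-individual variance sa2 and noise variance se2, two genes with
    loadings (b, s*b) on a common standard-normal factor have correlation
    (sa2 + s*b^2) / (sa2 + b^2 + se2).  Solving for b^2 given the sign branch:
    positive product when r > sa2/(sa2+se2), else negative (one loading
    negated).  Exact for every |r| < 1 as long as sa2 + se2 > 0.
    """
    sa2 = individual_effect_sd**2
    se2 = noise_sd**2
    v0 = sa2 + se2
    if v0 <= 0:
        raise InfeasibleLoadingError(
            f"pair {pair}: cannot plant r={r} with zero noise and zero individual effect"
        )
    rho0 = sa2 / v0
    if r >= rho0:
        b2 = (r * v0 - sa2) / (1.0 - r)
        sign = 1.0
    else:
        b2 = (sa2 - r * v0) / (1.0 + r)
        sign = -1.0
    if b2 < 0:
        raise InfeasibleLoadingError(f"pair {pair}: requested r={r} unreachable")
    return float(np.sqrt(b2)), sign


def generate_study(config: SyntheticConfig) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Generate a paired baseline/stress study with planted truth.

    Deterministic given ``config.seed``.  Returns the study and a
    :class:`SyntheticTruth` echoing the planted parameters (phenotype unset;
    see :func:`generate_phenotype`).
    """
    rng = np.random.default_rng([config.seed, 0])
    G, N = config.n_genes, config.n_individuals
    conditions = (BASELINE, STRESS)

    mu = rng.normal(8.0, 1.0, size=G)
    a = rng.normal(0.0, config.individual_effect_sd, size=N)

    pair_members = {g for p in config.rewired_pairs for g in p[:2]}
    x = {c: np.tile(mu[:, None], (1, N)) + a[None, :] for c in conditions}

    if config.n_blocks > 0 and config.block_loading > 0:
        block_of = np.arange(G) % config.n_blocks
        for c in conditions:
            F = rng.normal(size=(config.n_blocks, N))
            contrib = config.block_loading * F[block_of, :]
            contrib[list(pair_members), :] = 0.0  # pair genes stay out of blocks
            x[c] += contrib

    for gi, gj, rb, rs in config.rewired_pairs:
        for c, r in ((BASELINE, rb), (STRESS, rs)):
            b, sign = _pair_loading(r, config.noise_sd, config.individual_effect_sd,
                                    (gi, gj))
            P = rng.normal(size=N)
            x[c][gi] += b * P
            x[c][gj] += sign * b * P

    for g, eff in config.de_genes:
        x[STRESS][g] += eff

    for c in conditions:
        x[c] += rng.normal(0.0, config.noise_sd, size=(G, N))

    gene_ids = pd.Index([f"g{g:04d}" for g in range(G)], name="gene_id")
    ind_ids = [f"ind{i:03d}" for i in range(N)]
    matrices, meta_rows = {}, []
    for c in conditions:
        cols = [f"{c}_{i}" for i in ind_ids]
        matrices[c] = pd.DataFrame(x[c], index=gene_ids, columns=cols)
        meta_rows += [(s, i, c) for s, i in zip(cols, ind_ids)]
    samples = pd.DataFrame(meta_rows, columns=["sample_id", "individual_id", "condition"])
    samples = samples.set_index("sample_id")

    study = ExpressionStudy(matrices=matrices, samples=samples)
    truth = SyntheticTruth(
        de_genes=tuple(config.de_genes),
        rewired_pairs=tuple(config.rewired_pairs),
        phenotype_genes=tuple(config.phenotype_genes),
    )
    return study, truth


def generate_detection_calls(study: ExpressionStudy,
                             config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """MAS5-style detection calls ('P'/'A') per condition.

    Every gene×sample cell is called present independently with probability
    ``present_fraction``, except genes listed in ``low_presence_genes`` which
    use ``low_presence_fraction`` instead (to exercise the presence filter).
    Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = study.gene_ids
    low = set(config.low_presence_genes)
    p = np.full(len(gene_ids), config.present_fraction)
    if low:
        p[list(low)] = config.low_presence_fraction
    calls = {}
    for cond, mat in study.matrices.items():
        u = rng.random(size=mat.shape)
        arr = np.where(u < p[:, None], "P", "A")
        calls[cond] = pd.DataFrame(arr, index=gene_ids, columns=mat.columns)
    return calls


def generate_phenotype(study: ExpressionStudy, truth: SyntheticTruth,
                       config: SyntheticConfig) -> pd.Series:
    """Per-individual log2 phenotype driven by planted genes' expression change.

    phenotype_i = sum_g effect_g * (x_stress − x_baseline)_{g,i} + noise, with
    noise ~ N(0, phenotype_noise_sd^2).  With no phenotype genes the result is
    pure noise.  The returned Series is also stored on ``truth.phenotype``.
    """
    rng = np.random.default_rng([config.seed, 2])
    paired = study.paired_individuals(BASELINE, STRESS)
    base_cols = study.individuals(BASELINE)
    stress_cols = study.individuals(STRESS)
    bcol = {v: k for k, v in base_cols.items()}
    scol = {v: k for k, v in stress_cols.items()}
    pheno = rng.normal(0.0, config.phenotype_noise_sd, size=len(paired))
    gene_ids = study.gene_ids
    for g, eff in truth.phenotype_genes:
        gid = gene_ids[g]
        delta = np.array(
            [study.matrices[STRESS].at[gid, scol[i]]
             - study.matrices[BASELINE].at[gid, bcol[i]] for i in paired]
        )
        pheno = pheno + eff * delta
    series = pd.Series(pheno, index=pd.Index(paired, name="individual_id"),
                       name="phenotype")
    truth.phenotype = series
    return series


def generate_all(config: SyntheticConfig):
    """Convenience: study, truth (with phenotype) and detection calls."""
    study, truth = generate_study(config)
    calls = generate_detection_calls(study, config)
    generate_phenotype(study, truth, config)
    return study, truth, calls


def generate_module_switch_study(
    n_genes: int = 100,
    n_individuals: int = 100,
    n_switch: int = 5,
    module_size: int = 20,
    loading: float = 1.0,
    noise_sd: float = 0.5,
    switch: bool = True,
    seed: int = 0,
) -> tuple[ExpressionStudy, dict[str, list[str]]]:
    """Study where planted genes change their generating weights under stress.

    Two coexpression modules are driven by per-condition standard-normal
    factors F1 and F2, each with ``module_size`` member genes at loading
    ``loading`` over noise ``noise_sd``.  The first ``n_switch`` genes are
    rewiring targets: they follow F1 at baseline and F2 under stress (or F1
    in both conditions when ``switch=False`` — the matched null study).  The
    module's redundancy mirrors real coexpression data, where a well-modeled
    gene is predicted by many correlated partners; with the defaults a
    target's model-attainable R² is loading²/(loading²+noise_sd²) = 0.8,
    the regime reported for well-predicted genes.  Remaining genes are
    independent noise.

    Returns the study and a partition of the genes:
    ``switch`` (the planted rewiring targets), ``module1``/``module2``
    (members of the two modules — note their correlations with the switch
    genes also change under stress, so they are NOT interaction-nulls), and
    ``null`` (the independent noise genes, whose interactions are unchanged).
    """
    if n_switch + 2 * module_size > n_genes:
        raise ValueError("n_genes too small for modules plus switch targets")
    rng = np.random.default_rng([seed, 3])
    genes = pd.Index([f"g{g:04d}" for g in range(n_genes)], name="gene_id")
    mu = rng.normal(8.0, 1.0, size=n_genes)
    m1 = slice(n_switch, n_switch + module_size)
    m2 = slice(n_switch + module_size, n_switch + 2 * module_size)
    matrices, rows = {}, []
    for cond in (BASELINE, STRESS):
        f1 = rng.normal(size=n_individuals)
        f2 = rng.normal(size=n_individuals)
        x = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_individuals))
        x[m1] += loading * f1
        x[m2] += loading * f2
        x[:n_switch] += loading * (f2 if (switch and cond == STRESS) else f1)
        cols = [f"{cond}_ind{i:03d}" for i in range(n_individuals)]
        matrices[cond] = pd.DataFrame(x, index=genes, columns=cols)
        rows += [(s, f"ind{i:03d}", cond) for i, s in enumerate(cols)]
    samples = pd.DataFrame(rows, columns=["sample_id", "individual_id",
                                          "condition"]).set_index("sample_id")
    partition = {
        "switch": list(genes[:n_switch]),
        "module1": list(genes[m1]),
        "module2": list(genes[m2]),
        "null": list(genes[n_switch + 2 * module_size:]),
    }
    return ExpressionStudy(matrices=matrices, samples=samples), partition


def write_study(study: ExpressionStudy, out_dir: str | Path,
                truth: SyntheticTruth | None = None,
                calls: dict[str, pd.DataFrame] | None = None) -> None:
    """Write a study (and optionally truth/calls/phenotype) as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, mat in study.matrices.items():
        mat.to_csv(out / f"expression_{cond}.tsv", sep="\t", index_label="gene_id")
    study.samples.to_csv(out / "samples.tsv", sep="\t")
    if calls is not None:
        for cond, cm in calls.items():
            cm.to_csv(out / f"calls_{cond}.tsv", sep="\t", index_label="gene_id")
    if truth is not None:
        truth.to_json(out / "truth.json")
        if truth.phenotype is not None:
            truth.phenotype.to_csv(out / "phenotype.tsv", sep="\t")


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain dict (YAML/JSON block), tuplifying lists."""
    kw = dict(d)
    for key in ("rewired_pairs", "de_genes", "phenotype_genes", "low_presence_genes"):
        if key in kw:
            kw[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                            for v in kw[key])
    return SyntheticConfig(**kw)
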