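"""Reading, writing and preprocessing of expression studies.

Reproduces the standard microarray preprocessing chain of the analysis:
probeset → gene collapsing (excluding cross-hybridizing ``x_at`` probesets,
picking one probeset per gene at random), MAS5-style present-call filtering
("present in at least 80% of samples in either condition"), per-sample
trimmed-mean scaling to a target intensity followed by log2, and the
fold-change-matrix variant that normalizes each individual's stress response
against their own baseline.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "read_study",
    "write_study",
    "collapse_probesets",
    "present_filter",
    "scale_and_log",
    "fold_change_matrix",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column = gene IDs). Fails loudly on
    non-numeric cells and duplicated gene IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene IDs in {path}: {dup[:5]}")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc


def read_study(expression_tsvs: dict[str, str | Path],
               metadata_tsv: str | Path) -> ExpressionStudy:
    """Assemble an :class:`ExpressionStudy` from per-condition TSVs + metadata.

    ``expression_tsvs`` maps condition label → matrix path.  Every sample
    column must appear in the metadata (sample_id, individual_id, condition);
    gene order is taken from the files and must agree across conditions.
    """
    meta = pd.read_csv(metadata_tsv, sep="\t", index_col="sample_id")
    matrices = {}
    for cond, path in expression_tsvs.items():
        mat = read_matrix_tsv(path)
        missing = [s for s in mat.columns if s not in meta.index]
        if missing:
            raise ValueError(
                f"sample(s) {missing} in condition {cond!r} absent from metadata"
            )
        matrices[cond] = mat
    study = ExpressionStudy(matrices=matrices, samples=meta)
    study.validate()
    return study


def write_study(study: ExpressionStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, mat in study.matrices.items():
        mat.to_csv(out / f"expression_{cond}.tsv", sep="\t", index_label="gene_id")
    study.samples.to_csv(out / "samples.tsv", sep="\t")


def read_probeset_map(path: str | Path) -> pd.DataFrame:
    pmap = pd.read_csv(path, sep="\t")
    if pmap.empty:
        raise ValueError("empty probeset map")
    return pmap.set_index("probeset_id")


def collapse_probesets(matrix: pd.DataFrame, probeset_map: pd.DataFrame,
                       seed: int = 0) -> pd.DataFrame:
    """Collapse a probeset-indexed matrix to one row per gene.

    Probesets whose ID ends in ``x_at`` (cross-hybridizing) are dropped
    first; for a gene measured by several remaining probesets exactly one is
    chosen uniformly at random from a dedicated seeded stream, so collapsing
    is reproducible independently of any other randomness.  Genes left with
    only ``x_at`` probesets are dropped and logged.
    """
    missing = [p for p in matrix.index if p not in probeset_map.index]
    if missing:
        raise ValueError(f"probesets absent from map: {missing[:5]}")
    rng = np.random.default_rng(seed)
    eligible = [p for p in matrix.index if not str(p).endswith("x_at")]
    gene_of = probeset_map["gene_symbol"]
    by_gene: dict[str, list] = {}
    for p in eligible:
        by_gene.setdefault(gene_of[p], []).append(p)
    dropped = sorted(set(gene_of[list(matrix.index)]) - set(by_gene))
    if dropped:
        logger.warning("genes with only x_at probesets dropped: %s", dropped)
    chosen = {}
    for gene in by_gene:  # insertion order = file order, stable under the seed
        probes = by_gene[gene]
        chosen[gene] = probes[0] if len(probes) == 1 else probes[rng.integers(len(probes))]
    out = matrix.loc[[chosen[g] for g in chosen]]
    out.index = pd.Index(list(chosen), name="gene_id")
    return out


def present_filter(calls: dict[str, pd.DataFrame], threshold: float = 0.8) -> list:
    """Genes called 'P' in at least ``threshold`` of samples in EITHER condition.

    The fraction is computed against each condition's own sample count;
    marginal ('M') calls count as not-present.  The threshold is inclusive.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not calls or any(df.empty for df in calls.values()):
        raise ValueError("empty detection calls")
    keep = None
    genes = None
    for cond, df in calls.items():
        frac = (df.to_numpy() == "P").mean(axis=1)
        ok = frac >= threshold
        if keep is None:
            keep, genes = ok, list(df.index)
        else:
            if list(df.index) != genes:
                raise ValueError("gene order differs between call matrices")
            keep = keep | ok
    return [g for g, k in zip(genes, keep) if k]


def scale_and_log(raw: pd.DataFrame, target: float = 500.0,
                  trim: float = 0.02) -> pd.DataFrame:
    """Per-sample trimmed-mean scaling to ``target`` intensity, then log2.

    Each sample (column) is multiplied by a constant so its two-sided
    ``trim``-trimmed mean equals ``target`` (the MAS5 "scaled to 500"
    convention); values below 1 are clamped to 1 before the log so the output
    stays nonnegative.  Scale-invariant: doubling the raw input changes
    nothing.
    """
    arr = raw.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("raw intensities must be nonnegative")
    tmeans = np.array([stats.trim_mean(arr[:, j], trim) for j in range(arr.shape[1])])
    zero = np.flatnonzero(tmeans <= 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {list(raw.columns[zero])}")
    scaled = arr * (target / tmeans)[None, :]
    return pd.DataFrame(np.log2(np.clip(scaled, 1.0, None)),
                        index=raw.index, columns=raw.columns)


def fold_change_matrix(study: ExpressionStudy, baseline_label: str,
                       stress_label: str) -> pd.DataFrame:
    """Per-individual log2 fold change matrix (stress − baseline).

    Columns are the individuals paired across the two conditions; unpaired
    individuals are excluded and logged.  With matrices already on the log2
    scale the entry is simply the difference, i.e. log2 of the linear fold.
    """
    paired = study.paired_individuals(baseline_label, stress_label)
    if not paired:
        raise ValueError(
            f"no individuals paired between {baseline_label!r} and {stress_label!r}"
        )
    all_inds = set(study.individuals(baseline_label)) | set(
        study.individuals(stress_label))
    unpaired = sorted(all_inds - set(paired))
    if unpaired:
        logger.info("excluding %d unpaired individuals: %s",
                    len(unpaired), unpaired[:5])
    b_ind = study.individuals(baseline_label)
    s_ind = study.individuals(stress_label)
    b_col = {v: k for k, v in b_ind.items()}
    s_col = {v: k for k, v in s_ind.items()}
    base = study.matrices[baseline_label][[b_col[i] for i in paired]]
    stress = study.matrices[stress_label][[s_col[i] for i in paired]]
    out = pd.DataFrame(stress.to_numpy() - base.to_numpy(),
                       index=study.gene_ids, columns=paired)
    out.columns.name = "individual_id"
    return out
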