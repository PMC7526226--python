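"""Unsupervised structure in differentially expressed genes.

Genes are clustered hierarchically on correlation distance
(1 - Pearson) with complete linkage; the number of clusters is chosen
by a non-negative matrix factorization rank survey (consensus
clustering over seeded runs, scored by cophenetic correlation with
reconstruction residual as tie-break) and applied as a manual cut of
the dendrogram. Cluster behavior is summarized as median expression
trajectories per genotype and age, overlap with aging gene sets, and
module eigengenes (PC1 across samples) correlated with genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .core import ExpressionMatrix
from .de import size_factors_median_of_ratios

__all__ = [
    "RankSurveyResult",
    "normalized_log2",
    "hcluster_genes",
    "cut_to_k",
    "nmf_rank_survey",
    "cluster_trajectories",
    "cluster_aging_overlap",
    "module_eigengene",
    "Eigengene",
]


def normalized_log2(matrix: ExpressionMatrix, log_scale: bool = True) -> pd.DataFrame:
    """Depth-normalized expression (median-of-ratios), optionally
    log2(x+1)-transformed — the input convention for the clustering
    routines here."""
    sf = size_factors_median_of_ratios(matrix)
    norm = matrix.values / sf
    return np.log2(norm + 1.0) if log_scale else norm


def hcluster_genes(expr: pd.DataFrame):
    """Complete-linkage agglomeration on 1 - Pearson distance.

    ``expr`` is genes x samples (already normalized). Zero-variance
    genes cannot be correlated and are excluded; the returned linkage
    is annotated with the clustered gene ids (``linkage.gene_ids``).
    """
    arr = expr.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    var = arr.var(axis=1)
    keep = var > 0
    arr = arr[keep]
    gene_ids = list(np.asarray(expr.index)[keep])
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(arr)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return _Linkage(linkage, gene_ids)


@dataclass
class _Linkage:
    """Merge history plus the gene ids it refers to."""

    matrix: np.ndarray
    gene_ids: list


def cut_to_k(linkage: _Linkage, k: int) -> pd.Series:
    """Cut the dendrogram into exactly k clusters.

    Returns gene_id -> cluster label (1..k). Labels are contiguous and
    renumbered in order of first appearance for reproducibility.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(linkage.gene_ids)
    if k > n:
        raise ValueError("k exceeds number of genes")
    raw = hierarchy.fcluster(linkage.matrix, t=k, criterion="maxclust")
    # renumber by first appearance
    seen: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return pd.Series(labels, index=linkage.gene_ids, name="cluster")


@dataclass(frozen=True)
class RankSurveyResult:
    survey: pd.DataFrame  # columns: rank, cophenetic, residual
    chosen_rank: int


def _consensus_cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation between consensus distances and their
    average-linkage hierarchical representation."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0 if np.allclose(condensed, 0.0) else 0.0
    link = hierarchy.linkage(condensed, method="average")
    coph, _ = hierarchy.cophenet(link, condensed)
    return float(coph)


def nmf_rank_survey(
    expr: pd.DataFrame | np.ndarray,
    ranks,
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 500,
) -> RankSurveyResult:
    """Survey NMF ranks by consensus-clustering stability.

    For each candidate rank r, the non-negative genes x samples matrix
    is factorized ``n_runs`` times from seeded random starts
    (multiplicative updates, Frobenius objective); genes are assigned
    to their dominant basis component, run-wise co-assignments are
    averaged into a consensus matrix, and the rank is scored by the
    cophenetic correlation of that consensus (residual = best
    reconstruction error as tie-break). Chosen rank maximizes the
    cophenetic score, breaking ties toward smaller residual.
    """
    arr = np.asarray(expr, dtype=float)
    if (arr < 0).any():
        raise ValueError("NMF requires non-negative input")
    n = arr.shape[0]
    rows = []
    rng = np.random.default_rng(seed)
    for r in ranks:
        if r < 2 or r >= min(arr.shape):
            continue
        consensus = np.zeros((n, n))
        best_resid = np.inf
        for _ in range(n_runs):
            run_seed = int(rng.integers(0, 2**31 - 1))
            model = NMF(
                n_components=int(r),
                init="random",
                solver="mu",
                beta_loss="frobenius",
                max_iter=max_iter,
                random_state=run_seed,
                tol=1e-5,
            )
            with warnings.catch_warnings():
                # a capped iteration budget per run is intentional; the
                # consensus aggregation absorbs per-run slack
                warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(arr)
            assign = W.argmax(axis=1)
            consensus += (assign[:, None] == assign[None, :]).astype(float)
            best_resid = min(best_resid, float(model.reconstruction_err_))
        consensus /= n_runs
        rows.append(
            {
                "rank": int(r),
                "cophenetic": _consensus_cophenetic(consensus),
                "residual": best_resid,
            }
        )
    if not rows:
        raise ValueError("no feasible rank in survey")
    survey = pd.DataFrame(rows)
    best = survey.sort_values(
        ["cophenetic", "residual", "rank"], ascending=[False, True, True]
    ).iloc[0]
    return RankSurveyResult(survey=survey, chosen_rank=int(best["rank"]))


def cluster_trajectories(
    assignment: pd.Series, expr: pd.DataFrame, metadata: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Median expression of each cluster per (genotype, age).

    The median is taken over member genes and all replicates of the
    cell, on normalized expression; reported log2(x+1)-transformed by
    default. Returns a tidy frame (cluster, genotype, age, median).
    """
    rows = []
    for cluster, genes in assignment.groupby(assignment):
        sub = expr.loc[genes.index]
        for (g, a), meta_cell in metadata.groupby(["genotype", "age"], sort=True):
            vals = sub.loc[:, list(meta_cell["sample_id"])].to_numpy().ravel()
            med = float(np.median(vals))
            rows.append(
                {
                    "cluster": int(cluster),
                    "genotype": g,
                    "age": a,
                    "median": np.log2(med + 1.0) if log_transform else med,
                }
            )
    return pd.DataFrame(rows)


def cluster_aging_overlap(assignment: pd.Series, aging_de_sets) -> pd.Series:
    """Fraction of each cluster's genes found in the union of aging DE
    sets (e.g. the three pairwise age-contrast significant sets)."""
    union: set = set()
    for s in aging_de_sets:
        union |= set(s)
    frac = {
        int(c): float(np.mean([g in union for g in genes.index]))
        for c, genes in assignment.groupby(assignment)
    }
    return pd.Series(frac, name="aging_overlap_fraction")


@dataclass(frozen=True)
class Eigengene:
    module_label: str
    scores: pd.Series  # per-sample, unit norm
    genotype_correlation: float
    p_value: float


def module_eigengene(
    expr: pd.DataFrame,
    module_genes,
    metadata: pd.DataFrame,
    reference_genotype: str = "control",
    label: str = "module",
) -> Eigengene:
    """Module eigengene: PC1 loadings of the module across samples.

    The module submatrix is gene-standardized, its first right singular
    vector over samples is the eigengene (unit norm, oriented so that
    its correlation with mean module expression is non-negative), and
    the genotype association is the Pearson correlation between the
    eigengene and a 0/1 non-reference-genotype indicator, tested with
    the usual t approximation (needs >= 3 samples).
    """
    genes = [g for g in module_genes if g in expr.index]
    if len(genes) < 2:
        raise ValueError("module needs at least 2 genes present in the matrix")
    sub = expr.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        sub = sub[sd > 0]
        if sub.shape[0] < 2:
            raise ValueError("fewer than 2 genes with nonzero variance")
        sd = sd[sd > 0]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    scores = pd.Series(eig, index=expr.columns, name="eigengene")
    n = len(scores)
    if n < 3:
        raise ValueError("fewer than 3 samples; correlation undefined")
    indicator = (
        metadata.set_index("sample_id")
        .loc[list(expr.columns), "genotype"]
        .ne(reference_genotype)
        .to_numpy(dtype=float)
    )
    r, p = stats.pearsonr(eig, indicator)
    return Eigengene(
        module_label=label,
        scores=scores,
        genotype_correlation=float(r),
        p_value=float(p),
    )
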