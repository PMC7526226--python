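"""Permutation-based empirical FDR for a chosen p-value threshold.

The BH threshold chosen on the observed data is audited by shuffling
genotype labels across samples, re-running the complete differential
expression fit (normalization, dispersion estimation, Wald tests) on
each shuffled dataset, and counting how many genes fall at or below the
threshold by chance. The empirical FDR is the mean null hit count over
permutations divided by the observed hit count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .de import DesignSpec, fit_nb_glm

__all__ = ["PermutationResult", "empirical_fdr"]


@dataclass(frozen=True)
class PermutationResult:
    n_permutations: int
    p_threshold: float
    observed_hits: int
    mean_null_hits: float
    empirical_fdr: float
    seed: int
    defined: bool = True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def empirical_fdr(
    matrix: ExpressionMatrix,
    design: DesignSpec,
    p_threshold: float,
    n_permutations: int = 1000,
    seed: int = 0,
    within_age: bool = False,
) -> PermutationResult:
    """Estimate the empirical FDR at ``p_threshold`` for one design.

    Genotype labels are shuffled across samples (age and replicate
    annotations untouched); with ``within_age=True`` the shuffle is
    blocked within each age level instead, preserving the genotype
    multiset per age. The full per-gene fit is re-run on every
    permutation. ``observed_hits == 0`` yields a result flagged
    undefined with ``empirical_fdr`` NaN.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    genotypes = matrix.metadata["genotype"].to_numpy()
    if len(np.unique(genotypes)) < 2:
        raise ValueError("need >= 2 genotype labels to permute")

    observed = fit_nb_glm(matrix, design)
    observed_hits = int((observed["pvalue"] <= p_threshold).sum())

    rng = np.random.default_rng(seed)
    ages = matrix.metadata["age"].to_numpy()
    null_hits = np.zeros(n_permutations)
    for b in range(n_permutations):
        perm = genotypes.copy()
        if within_age:
            for a in np.unique(ages):
                idx = np.flatnonzero(ages == a)
                perm[idx] = perm[rng.permutation(idx)]
        else:
            perm = perm[rng.permutation(len(perm))]
        meta = matrix.metadata.copy()
        meta["genotype"] = perm
        shuffled = ExpressionMatrix(matrix.values, meta, matrix.modality)
        try:
            res = fit_nb_glm(shuffled, design)
        except ValueError:
            # a shuffle can empty a genotype level within a stratum
            null_hits[b] = np.nan
            continue
        null_hits[b] = (res["pvalue"] <= p_threshold).sum()

    mean_null = float(np.nanmean(null_hits))
    if observed_hits > 0:
        fdr = min(1.0, mean_null / observed_hits)
        defined = True
    else:
        fdr = float("nan")
        defined = False
    return PermutationResult(
        n_permutations=n_permutations,
        p_threshold=p_threshold,
        observed_hits=observed_hits,
        mean_null_hits=mean_null,
        empirical_fdr=fdr,
        seed=seed,
        defined=defined,
    )
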