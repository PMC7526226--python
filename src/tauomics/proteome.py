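"""Label-free proteome preparation.

Order of operations mirrors a standard LFQ workflow: require complete
detection in at least one experimental (genotype x age) group, collapse
protein isoforms to gene symbols by averaging observed values, then
impute remaining missing values per sample from a down-shifted Gaussian
that emulates abundance near the detection limit. Missingness-
sensitivity subsets (fully observed / <50% missing) are provided for
downstream robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix

__all__ = [
    "ImputationParams",
    "filter_complete_in_group",
    "collapse_isoforms",
    "impute_downshift",
    "missingness_subsets",
]


@dataclass(frozen=True)
class ImputationParams:
    """Down-shift imputation parameters.

    Missing values in sample j are drawn from
    Normal(median_j - downshift_sd * sd_j, (width_sd * sd_j)^2),
    with median_j and sd_j computed over that sample's observed log2
    intensities. The 1.8-SD shift places imputed values near the
    detection limit; the 0.3-SD width is the convention of the
    Perseus-style imputation this emulates.
    """

    downshift_sd: float = 1.8
    width_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.downshift_sd < 0:
            raise ValueError("downshift_sd must be >= 0")
        if self.width_sd <= 0:
            raise ValueError("width_sd must be > 0")


def filter_complete_in_group(
    lfq: ExpressionMatrix, design=None
) -> ExpressionMatrix:
    """Keep proteins fully observed in at least one (genotype, age) group.

    Groups are taken from the matrix metadata; ``design``, when given,
    is cross-checked against the metadata's genotype/age levels.
    """
    meta = lfq.metadata
    if design is not None:
        if set(meta["genotype"]) - set(design.genotypes) or set(meta["age"]) - set(
            design.ages
        ):
            raise ValueError("metadata levels not covered by design")
    observed = lfq.values.notna().to_numpy()
    group_labels = list(zip(meta["genotype"], meta["age"]))
    keep = np.zeros(lfq.n_features, dtype=bool)
    for g in set(group_labels):
        cols = np.array([lbl == g for lbl in group_labels])
        keep |= observed[:, cols].all(axis=1)
    return lfq.subset_features(np.asarray(lfq.feature_ids)[keep])


def collapse_isoforms(lfq: ExpressionMatrix, isoform_map: pd.DataFrame) -> ExpressionMatrix:
    """Average protein isoforms of the same gene, missing-aware.

    ``isoform_map`` has columns ``isoform_id`` and ``gene_symbol``
    (many-to-one). Rows without a mapping are dropped. Per gene and
    sample the value is the arithmetic mean of the observed isoform
    intensities; it is missing only when every isoform is missing.
    """
    if not {"isoform_id", "gene_symbol"} <= set(isoform_map.columns):
        raise ValueError("isoform_map needs isoform_id and gene_symbol columns")
    mapping = isoform_map.dropna(subset=["gene_symbol"]).set_index("isoform_id")[
        "gene_symbol"
    ]
    if mapping.index.has_duplicates:
        raise ValueError("isoform mapped to more than one gene symbol")
    mapped = [f for f in lfq.feature_ids if f in mapping.index]
    vals = lfq.values.loc[mapped]
    genes = mapping.loc[mapped]
    collapsed = vals.groupby(genes.to_numpy()).mean()  # skipna mean; all-NaN -> NaN
    collapsed.index.name = lfq.values.index.name
    return ExpressionMatrix(collapsed, lfq.metadata.copy(), lfq.modality)


def impute_downshift(
    lfq: ExpressionMatrix,
    params: ImputationParams = ImputationParams(),
    log2_input: bool = True,
) -> ExpressionMatrix:
    """Impute missing values per sample from a down-shifted Gaussian.

    Expects log2-scale intensities; pass ``log2_input=False`` for raw
    intensities, which are log2-transformed, imputed, and returned on
    the raw scale. Observed values are never altered.
    """
    vals = lfq.values.to_numpy(dtype=float).copy()
    if not log2_input:
        with np.errstate(divide="ignore"):
            vals = np.log2(vals)
    rng = np.random.default_rng(params.seed)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        missing = ~np.isfinite(col)
        if not missing.any():
            continue
        obs = col[~missing]
        if obs.size < 2:
            raise ValueError(
                f"sample {lfq.sample_ids[j]!r}: <2 observed values, cannot estimate SD"
            )
        med, sd = np.median(obs), np.std(obs, ddof=1)
        col[missing] = rng.normal(
            med - params.downshift_sd * sd,
            params.width_sd * sd,
            size=int(missing.sum()),
        )
    if not log2_input:
        vals = 2.0**vals
    out = pd.DataFrame(vals, index=lfq.values.index, columns=lfq.values.columns)
    return ExpressionMatrix(out, lfq.metadata.copy(), lfq.modality)


def missingness_subsets(lfq: ExpressionMatrix):
    """(fully observed proteins, proteins with <50% missingness)."""
    frac_missing = lfq.values.isna().mean(axis=1).to_numpy()
    ids = np.asarray(lfq.feature_ids)
    no_missing = lfq.subset_features(ids[frac_missing == 0])
    lt50 = lfq.subset_features(ids[frac_missing < 0.5])
    return no_missing, lt50
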