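"""Shared containers for expression data and study design.

The analyses in this package all operate on a feature-by-sample matrix
(RNA-seq read counts or LFQ protein intensities) with per-sample
annotations for genotype, age, and replicate. Missing proteomic values
are encoded as NaN, never zero, so that absence of detection is not
conflated with low abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "ExpressionMatrix",
    "read_matrix_tsv",
    "read_metadata_tsv",
]

#: Required columns in sample metadata.
METADATA_COLUMNS = ("sample_id", "genotype", "age", "replicate")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial genotype x age design with replicated samples.

    Parameters
    ----------
    genotypes : tuple of str
        Genotype labels; ``control`` names the reference level.
    ages : tuple
        Ordered categorical age levels (days). Age is treated as a
        factor, not a continuous slope, throughout the package.
    replicates_per_cell : int
        Number of replicate samples in each (genotype, age) cell.
    control : str
        The genotype used as the reference in all models.
    """

    genotypes: tuple = ("control", "tau")
    ages: tuple = (1, 10, 20)
    replicates_per_cell: int = 3
    control: str = "control"

    def __post_init__(self):
        if len(self.genotypes) < 2:
            raise ValueError("need at least 2 genotypes")
        if len(self.ages) < 2:
            raise ValueError("need at least 2 age levels")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be positive")
        if self.control not in self.genotypes:
            raise ValueError(f"control {self.control!r} not in genotypes")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype labels")
        if len(set(self.ages)) != len(self.ages):
            raise ValueError("duplicate age levels")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.ages) * self.replicates_per_cell

    def metadata(self) -> pd.DataFrame:
        """Sample sheet with one row per sample.

        Sample ids encode genotype, age and replicate
        (``<genotype>_d<age>_r<rep>``) and are unique by construction.
        """
        rows = [
            {
                "sample_id": f"{g}_d{a}_r{r}",
                "genotype": g,
                "age": a,
                "replicate": r,
            }
            for g in self.genotypes
            for a in self.ages
            for r in range(1, self.replicates_per_cell + 1)
        ]
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values with sample annotations.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample. ``metadata`` has one row per sample (columns ``sample_id``,
    ``genotype``, ``age``, ``replicate``) aligned to the columns of
    ``values``. ``modality`` is ``"transcriptome"`` or ``"proteome"``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    modality: str = "transcriptome"

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        meta_ids = list(self.metadata["sample_id"])
        if list(self.values.columns) != meta_ids:
            missing = set(self.values.columns) - set(meta_ids)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            # allow metadata in different order; align it
            self.metadata = (
                self.metadata.set_index("sample_id")
                .loc[list(self.values.columns)]
                .reset_index()
            )
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("negative expression values")

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, mask) -> "ExpressionMatrix":
        """Restrict to samples where the boolean mask (aligned to
        metadata rows) is True."""
        mask = np.asarray(mask, dtype=bool)
        meta = self.metadata.loc[mask].reset_index(drop=True)
        vals = self.values.loc[:, list(meta["sample_id"])]
        return ExpressionMatrix(vals, meta, self.modality)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        vals = self.values.loc[list(feature_ids)]
        return ExpressionMatrix(vals, self.metadata.copy(), self.modality)

    def groups(self) -> pd.Series:
        """(genotype, age) experimental-group label per sample."""
        m = self.metadata
        return pd.Series(
            list(zip(m["genotype"], m["age"])), index=list(m["sample_id"])
        )

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(
    values_path: str | Path,
    metadata_path: str | Path,
    modality: str = "transcriptome",
) -> ExpressionMatrix:
    """Load a feature-by-sample TSV plus its sample sheet."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = read_metadata_tsv(metadata_path)
    return ExpressionMatrix(values, metadata, modality)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta
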