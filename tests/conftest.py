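"""Shared fixtures: simulated datasets and fitted DE results.

The heavier simulations are session-scoped so the parameter-recovery,
calibration, and acceptance checks share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from tauomics import (
    DesignSpec,
    SimParams,
    StudyDesign,
    filter_low_counts,
    fit_nb_glm,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def spiked_dataset(design):
    """Default synthetic transcriptome (10% DE genes) plus truth."""
    matrix, truth = simulate_transcriptome(SimParams(n_genes=2000, seed=1), design)
    return matrix, truth


@pytest.fixture(scope="session")
def spiked_joint_fit(spiked_dataset):
    matrix, truth = spiked_dataset
    res = fit_nb_glm(filter_low_counts(matrix), DesignSpec("genotype_plus_age"))
    return res.set_index("feature_id"), truth


@pytest.fixture(scope="session")
def null_joint_fit(design):
    """Joint-model fit on a 2000-gene null simulation (no DE at all)."""
    params = SimParams(n_genes=2000, frac_genotype_de=0.0, frac_age_de=0.0, seed=2)
    matrix, truth = simulate_transcriptome(params, design)
    res = fit_nb_glm(filter_low_counts(matrix), DesignSpec("genotype_plus_age"))
    return res, truth


@pytest.fixture
def toy_counts():
    """Tiny integer matrix with hand-checkable means and ratios."""
    values = pd.DataFrame(
        {
            "s1": [100, 10, 40, 1000, 49],
            "s2": [200, 20, 80, 2000, 49],
            "s3": [400, 40, 160, 4000, 49],
        },
        index=[f"g{i}" for i in range(5)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "genotype": ["control", "tau", "tau"],
            "age": [1, 1, 1],
            "replicate": [1, 1, 2],
        }
    )
    from tauomics import ExpressionMatrix

    return ExpressionMatrix(values, meta)
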