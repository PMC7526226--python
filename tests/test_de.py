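"""Differential-expression core: filtering, normalization, NB GLM, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauomics import (
    DesignSpec,
    ExpressionMatrix,
    SimParams,
    StudyDesign,
    bh_adjust,
    default_designs,
    filter_low_counts,
    fit_nb_glm,
    run_de_suite,
    simulate_transcriptome,
    size_factors_median_of_ratios,
)


def _matrix(values: np.ndarray, genotypes, ages=None, prefix="s"):
    n = values.shape[1]
    ages = ages if ages is not None else [1] * n
    meta = pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i}" for i in range(n)],
            "genotype": genotypes,
            "age": ages,
            "replicate": list(range(1, n + 1)),
        }
    )
    vals = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=meta["sample_id"]
    )
    return ExpressionMatrix(vals, meta)


class TestFilterLowCounts:
    def test_boundary_below_and_equal(self):
        m = _matrix(np.array([[49, 49, 49], [50, 50, 50]]), ["control", "tau", "tau"])
        kept = filter_low_counts(m, 50)
        assert kept.feature_ids == ["g1"]

    def test_matches_brute_force_means(self, toy_counts):
        kept = filter_low_counts(toy_counts, 50)
        expected = [
            g for g in toy_counts.feature_ids
            if toy_counts.values.loc[g].mean() >= 50
        ]
        assert kept.feature_ids == expected

    def test_empty_matrix_raises(self):
        m = _matrix(np.zeros((2, 2), dtype=int), ["control", "tau"])
        with pytest.raises(ValueError):
            filter_low_counts(m.subset_features([]), 50)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix(np.tile([[10], [20], [30]], (1, 4)), ["control"] * 2 + ["tau"] * 2)
        sf = size_factors_median_of_ratios(m)
        np.testing.assert_allclose(sf, 1.0)

    def test_doubled_column_doubles_factor(self):
        base = np.array([[10, 20], [100, 200], [7, 14]])
        m = _matrix(base, ["control", "tau"])
        sf = size_factors_median_of_ratios(m)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_hand_computed_medians(self):
        # 4 genes x 3 samples, all positive; oracle computed per the
        # definition: ratio to per-gene geometric mean, median per column
        vals = np.array(
            [[10, 20, 30], [40, 10, 20], [5, 5, 5], [100, 200, 100]], dtype=float
        )
        geo = np.exp(np.log(vals).mean(axis=1))
        expected = np.median(vals / geo[:, None], axis=0)
        m = _matrix(vals.astype(int), ["control", "tau", "tau"])
        np.testing.assert_allclose(size_factors_median_of_ratios(m), expected)

    def test_no_all_positive_gene_raises(self):
        m = _matrix(np.array([[0, 5], [3, 0]]), ["control", "tau"])
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(m)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_and_dominates(self, ps):
        """Step-up oracle: q_(i) = min over j>=i of p_(j) * m / j."""
        p = np.asarray(ps)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank, i in enumerate(order):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank, m)
            ]
            brute[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(adj, brute, atol=1e-12)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()

    def test_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestNBGLM:
    def test_no_signal_gene_flat(self):
        vals = np.full((1, 6), 100)
        m = _matrix(vals, ["control"] * 3 + ["tau"] * 3)
        res = fit_nb_glm(m, DesignSpec("genotype_stratified_by_age", stratum_age=1))
        assert res.loc[0, "log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc[0, "pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_strong_gene(self):
        """A gene simulated at log2FC=2 with low dispersion is recovered
        within +/-0.5 and called at p < 0.01."""
        rng = np.random.default_rng(42)
        mu = np.array([200.0] * 3 + [800.0] * 3)
        alpha = 0.05
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(40, 6))
        m = _matrix(y, ["control"] * 3 + ["tau"] * 3)
        unit_sf = pd.Series(1.0, index=m.sample_ids)
        res = fit_nb_glm(
            m, DesignSpec("genotype_stratified_by_age", stratum_age=1),
            size_factors=unit_sf,
        )
        med_lfc = res["log2fc"].median()
        assert abs(med_lfc - 2.0) < 0.5
        assert (res["pvalue"] < 0.01).mean() > 0.9

    def test_statsmodels_cross_check(self):
        """Coefficients and SEs match an independent GLM fit (statsmodels
        NegativeBinomial family) at the same fixed dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        mu = np.outer([150, 300, 80], [1] * 3 + [2.2] * 3)
        alpha = 0.1
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        m = _matrix(y, ["control"] * 3 + ["tau"] * 3)
        sf = size_factors_median_of_ratios(m)
        disp = np.full(3, alpha)
        res = fit_nb_glm(
            m, DesignSpec("genotype_stratified_by_age", stratum_age=1),
            dispersion=disp,
        )
        X = sm.add_constant(np.array([0.0] * 3 + [1.0] * 3))
        for i in range(3):
            fit = sm.GLM(
                y[i], X,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf.to_numpy()),
            ).fit()
            assert res.loc[i, "log2fc"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4
            )
            assert res.loc[i, "se"] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3
            )

    def test_depth_invariance(self, spiked_dataset):
        """Scaling one sample's counts by c changes its size factor by c
        and leaves log2FC estimates unchanged."""
        matrix, _ = spiked_dataset
        small = filter_low_counts(matrix).subset_features(
            filter_low_counts(matrix).feature_ids[:150]
        )
        scaled_vals = small.values.copy()
        scaled_vals.iloc[:, 0] = scaled_vals.iloc[:, 0] * 3
        scaled = ExpressionMatrix(scaled_vals, small.metadata.copy())
        sf0 = size_factors_median_of_ratios(small)
        sf1 = size_factors_median_of_ratios(scaled)
        ratio = (sf1 / sf0).to_numpy()
        assert ratio[0] / np.median(ratio[1:]) == pytest.approx(3.0, rel=1e-6)
        r0 = fit_nb_glm(small, DesignSpec("genotype_plus_age"))
        r1 = fit_nb_glm(scaled, DesignSpec("genotype_plus_age"))
        np.testing.assert_allclose(
            r0["log2fc"], r1["log2fc"], atol=0.02
        )

    def test_wald_sign_matches_lfc_sign(self, spiked_joint_fit):
        res, _ = spiked_joint_fit
        fitted = res[res["status"] == "ok"]
        assert (np.sign(fitted["stat"]) == np.sign(fitted["log2fc"])).all()

    def test_all_zero_gene_flagged_and_excluded_from_bh(self):
        vals = np.array([[0, 0, 0, 0, 0, 0], [100, 120, 90, 300, 280, 310]])
        m = _matrix(vals, ["control"] * 3 + ["tau"] * 3)
        res = fit_nb_glm(m, DesignSpec("genotype_stratified_by_age", stratum_age=1))
        assert res.loc[0, "status"] == "all_zero"
        assert np.isnan(res.loc[0, "pvalue"])
        # BH on the remaining single gene is the identity
        assert res.loc[1, "fdr"] == pytest.approx(res.loc[1, "pvalue"])

    def test_interaction_test_has_joint_df(self, design):
        matrix, _ = simulate_transcriptome(SimParams(n_genes=50, seed=8), design)
        res = fit_nb_glm(
            filter_low_counts(matrix), DesignSpec("genotype_by_age_interaction")
        )
        fitted = res[res["status"] != "all_zero"]
        assert (fitted["df"] == 2).all()
        assert (fitted["stat"] >= 0).all()


class TestRunDESuite:
    def test_recovery_on_default_synthetic(self, spiked_joint_fit):
        """Joint-model recall of true DE genes at FDR<0.05 exceeds 0.7
        for genes simulated at |log2FC| >= 1."""
        res, truth = spiked_joint_fit
        truth = truth.loc[res.index]
        strong = truth["is_genotype_de"] & (truth["true_log2fc"].abs() >= 1)
        recall = (res.loc[strong, "fdr"] < 0.05).mean()
        assert recall > 0.7

    def test_cross_sectional_uses_only_stratum_samples(self, design):
        matrix, _ = simulate_transcriptome(SimParams(n_genes=30, seed=4), design)
        from tauomics.de import _build_design

        spec = DesignSpec("genotype_stratified_by_age", stratum_age=10)
        _, _, _, mask = _build_design(matrix.metadata, spec)
        assert mask.sum() == 2 * design.replicates_per_cell
        assert set(matrix.metadata.loc[mask, "age"]) == {10}

    def test_cross_sectional_union_matches_set_algebra(self, design):
        """The unique-DE union across per-age analyses equals the
        brute-force union of the per-age significant sets."""
        matrix, _ = simulate_transcriptome(SimParams(n_genes=300, seed=6), design)
        ages = sorted(matrix.metadata["age"].unique())
        designs = [
            DesignSpec("genotype_stratified_by_age", stratum_age=a) for a in ages
        ]
        table = run_de_suite(matrix, None, designs)
        per_age_sets = [
            set(
                table.loc[
                    (table["analysis"] == f"day{a}_crosssectional")
                    & table["significant"],
                    "feature_id",
                ]
            )
            for a in ages
        ]
        union_from_table = set(
            table.loc[table["significant"], "feature_id"]
        )
        assert union_from_table == set().union(*per_age_sets)

    def test_proteome_requires_imputed_input(self, design):
        matrix, truth = simulate_transcriptome(SimParams(n_genes=20, seed=4), design)
        vals = matrix.values.astype(float)
        vals.iloc[0, 0] = np.nan
        prot = ExpressionMatrix(vals, matrix.metadata.copy(), "proteome")
        with pytest.raises(ValueError, match="impute"):
            run_de_suite(None, prot, [DesignSpec("genotype_plus_age")])
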