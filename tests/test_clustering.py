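"""Hierarchical clustering, NMF rank survey, trajectories, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from tauomics import (
    cluster_aging_overlap,
    cluster_trajectories,
    cut_to_k,
    hcluster_genes,
    module_eigengene,
    nmf_rank_survey,
)


def _expr(values, index=None, columns=None):
    return pd.DataFrame(
        values,
        index=index if index is not None else [f"g{i}" for i in range(values.shape[0])],
        columns=columns
        if columns is not None
        else [f"s{i}" for i in range(values.shape[1])],
    )


def _planted_blocks(n_per_block=20, n_blocks=3, n_samples=12, sep=8.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(n_blocks):
        profile = np.zeros(n_samples)
        profile[b * (n_samples // n_blocks) : (b + 1) * (n_samples // n_blocks)] = sep
        for _ in range(n_per_block):
            rows.append(profile + rng.normal(0, noise, n_samples) + 10.0)
            labels.append(b)
    return _expr(np.array(rows)), np.array(labels)


class TestHcluster:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        vals = np.vstack([base, base, rng.normal(size=8), rng.normal(size=8) + 3])
        link = hcluster_genes(_expr(vals))
        first = link.matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_is_two(self):
        x = np.arange(6.0)
        link = hcluster_genes(_expr(np.vstack([x, -x])))
        assert link.matrix[0, 2] == pytest.approx(2.0)

    def test_merge_heights_match_brute_force_complete_linkage(self):
        """5-gene oracle: complete linkage recomputed by exhaustive
        max-pairwise-distance agglomeration."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 10))
        link = hcluster_genes(_expr(vals))

        # independent oracle
        corr = np.corrcoef(vals)
        d = 1 - corr
        clusters = {i: {i} for i in range(5)}
        heights = []
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a >= b:
                        continue
                    h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                    if best is None or h < best[0]:
                        best = (h, a, b)
            h, a, b = best
            heights.append(h)
            clusters[a] |= clusters.pop(b)
        np.testing.assert_allclose(sorted(link.matrix[:, 2]), sorted(heights), atol=1e-12)

    def test_zero_variance_gene_excluded(self):
        vals = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0)[::-1]])
        link = hcluster_genes(_expr(vals))
        assert "g0" not in link.gene_ids

    def test_heights_nondecreasing_ultrametric(self):
        rng = np.random.default_rng(2)
        link = hcluster_genes(_expr(rng.normal(size=(20, 8))))
        heights = link.matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestCutToK:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(3)
        link = hcluster_genes(_expr(rng.normal(size=(7, 6))))
        singletons = cut_to_k(link, 7)
        assert singletons.nunique() == 7
        one = cut_to_k(link, 1)
        assert one.nunique() == 1
        with pytest.raises(ValueError):
            cut_to_k(link, 0)

    def test_planted_two_blocks_recovered(self):
        expr, labels = _planted_blocks(n_blocks=2, n_per_block=15, seed=4)
        link = hcluster_genes(expr)
        assign = cut_to_k(link, 2)
        assert adjusted_rand_score(labels, assign.to_numpy()) == 1.0


class TestNMFRankSurvey:
    def test_planted_rank_three_selected(self):
        # moderate noise: enough that over-splitting the 3 blocks is
        # unstable across runs, so consensus stability peaks at 3
        expr, labels = _planted_blocks(
            n_blocks=3, n_per_block=15, sep=4.0, noise=1.0, seed=5
        )
        survey = nmf_rank_survey(expr, ranks=[2, 3, 4, 5], n_runs=8, seed=6)
        assert survey.chosen_rank == 3
        # and cutting the dendrogram at the surveyed rank recovers the blocks
        assign = cut_to_k(hcluster_genes(expr), survey.chosen_rank)
        assert adjusted_rand_score(labels, assign.to_numpy()) == 1.0

    def test_determinism(self):
        expr, _ = _planted_blocks(seed=7)
        s1 = nmf_rank_survey(expr, [2, 3], n_runs=4, seed=8)
        s2 = nmf_rank_survey(expr, [2, 3], n_runs=4, seed=8)
        pd.testing.assert_frame_equal(s1.survey, s2.survey)
        assert s1.chosen_rank == s2.chosen_rank

    def test_binary_block_consensus_has_perfect_cophenetic(self):
        from tauomics.clustering import _consensus_cophenetic

        consensus = np.kron(np.eye(3), np.ones((4, 4)))
        assert _consensus_cophenetic(consensus) == pytest.approx(1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nmf_rank_survey(np.array([[1.0, -1.0], [0.5, 2.0]]), [2])


class TestTrajectoriesAndOverlap:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "genotype": ["control"] * 4 + ["tau"] * 4,
                "age": [1, 1, 10, 10] * 2,
                "replicate": [1, 2] * 4,
            }
        )

    def test_single_gene_cluster_equals_its_cell_medians(self, meta):
        vals = _expr(np.arange(8.0)[None, :], index=["g0"], columns=meta["sample_id"])
        assign = pd.Series([1], index=["g0"])
        traj = cluster_trajectories(assign, vals, meta, log_transform=False)
        cell = traj.set_index(["genotype", "age"])["median"]
        assert cell[("control", 1)] == pytest.approx(np.median([0, 1]))
        assert cell[("tau", 10)] == pytest.approx(np.median([6, 7]))

    def test_scripted_cluster_median_hand_computed(self, meta):
        vals = _expr(
            np.array([[1.0] * 8, [3.0] * 8, [10.0] * 8]), columns=meta["sample_id"]
        )
        assign = pd.Series([1, 1, 1], index=vals.index)
        traj = cluster_trajectories(assign, vals, meta, log_transform=False)
        assert (traj["median"] == 3.0).all()

    def test_constant_matrix_flat_trajectories(self, meta):
        vals = _expr(np.full((4, 8), 7.0), columns=meta["sample_id"])
        assign = pd.Series([1, 1, 2, 2], index=vals.index)
        traj = cluster_trajectories(assign, vals, meta)
        assert traj["median"].nunique() == 1

    def test_aging_overlap_extremes_and_scripted(self):
        assign = pd.Series([1, 1, 2, 2], index=["a", "b", "c", "d"])
        everything = cluster_aging_overlap(assign, [{"a", "b", "c", "d"}])
        assert (everything == 1.0).all()
        nothing = cluster_aging_overlap(assign, [{"x"}, {"y"}])
        assert (nothing == 0.0).all()
        partial = cluster_aging_overlap(assign, [{"a"}, {"c", "d"}])
        assert partial[1] == pytest.approx(0.5)
        assert partial[2] == pytest.approx(1.0)


class TestModuleEigengene:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "genotype": ["control"] * 3 + ["tau"] * 3,
                "age": [1, 10, 20] * 2,
                "replicate": [1] * 6,
            }
        )

    def test_identical_genes_rank_one_module(self, meta):
        profile = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0])
        vals = _expr(np.vstack([profile, profile, profile]), columns=meta["sample_id"])
        e = module_eigengene(vals, vals.index, meta)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(e.scores, z)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self, meta):
        rng = np.random.default_rng(9)
        vals = _expr(rng.normal(size=(4, 6)), columns=meta["sample_id"])
        e = module_eigengene(vals, vals.index, meta)

        arr = vals.to_numpy()
        z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
        v = np.ones(6) / np.sqrt(6)
        for _ in range(500):
            v = z.T @ (z @ v)
            v /= np.linalg.norm(v)
        dot = abs(np.dot(v, e.scores.to_numpy()))
        assert dot == pytest.approx(1.0, abs=1e-6)

    def test_orientation_nonnegative_against_module_mean(self, meta):
        rng = np.random.default_rng(10)
        for seed in range(5):
            vals = _expr(
                np.random.default_rng(seed).normal(size=(5, 6)),
                columns=meta["sample_id"],
            )
            e = module_eigengene(vals, vals.index, meta)
            arr = vals.to_numpy()
            z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
            assert np.dot(e.scores, z.mean(axis=0)) >= 0

    def test_genotype_correlation_detects_separation(self, meta):
        base = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        rng = np.random.default_rng(11)
        vals = _expr(
            np.vstack([base + rng.normal(0, 0.1, 6) for _ in range(4)]),
            columns=meta["sample_id"],
        )
        e = module_eigengene(vals, vals.index, meta)
        assert abs(e.genotype_correlation) > 0.99
        assert e.p_value < 0.01

    def test_too_few_genes_raises(self, meta):
        vals = _expr(np.ones((1, 6)), columns=meta["sample_id"])
        with pytest.raises(ValueError):
            module_eigengene(vals, vals.index, meta)


def test_label_permutation_invariance():
    """Relabeling (reordering) genes permutes assignments identically."""
    expr, _ = _planted_blocks(n_per_block=6, seed=12)
    link = hcluster_genes(expr)
    assign = cut_to_k(link, 3)
    perm = np.random.default_rng(13).permutation(len(expr))
    expr_perm = expr.iloc[perm]
    assign_perm = cut_to_k(hcluster_genes(expr_perm), 3)
    assert adjusted_rand_score(
        assign.loc[expr_perm.index].to_numpy(), assign_perm.to_numpy()
    ) == 1.0
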