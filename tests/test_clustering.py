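"""Expression-structure discovery: filtering, NMF, hclust, PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crcinvasion import (
    filter_expressed,
    generate_expression_cohort,
    linkage_to_newick,
    nmf_factorize,
    pca_embed,
    select_rank,
    top_loading_genes,
    top_variable_hclust,
)
from crcinvasion.synthetic import CohortConfig, SignatureSpec, canine_cohort_config


def planted_block_matrix(seed=0, block_mean=10.0, off=0.1, noise=0.3,
                         genes_per_block=25, samples_per_block=6, k=4):
    rng = np.random.default_rng(seed)
    n_genes, n_samples = genes_per_block * k, samples_per_block * k
    X = np.full((n_genes, n_samples), off)
    for b in range(k):
        X[
            b * genes_per_block : (b + 1) * genes_per_block,
            b * samples_per_block : (b + 1) * samples_per_block,
        ] = block_mean
    X += rng.normal(0, noise, size=X.shape)
    X = np.clip(X, 0, None)
    truth = np.repeat(np.arange(k), samples_per_block)
    return (
        pd.DataFrame(
            X,
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{j:02d}" for j in range(n_samples)],
        ),
        truth,
    )


class TestFilterExpressed:
    def test_all_zero_gene_removed(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0]], index=["dead", "alive"], columns=["a", "b"]
        )
        out = filter_expressed(m)
        assert list(out.index) == ["alive"]

    def test_single_sample_expression_is_enough(self):
        m = pd.DataFrame(
            [[0.5, 0.0], [0.0, 0.0]], index=["g1", "g2"], columns=["a", "b"]
        )
        assert list(filter_expressed(m, 1).index) == ["g1"]

    def test_counting_oracle_on_zero_inflated_matrix(self):
        rng = np.random.default_rng(3)
        X = rng.normal(2, 1, size=(200, 10)) * (rng.uniform(size=(200, 10)) > 0.6)
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(200)])
        expected = int(((X > 0).sum(axis=1) >= 2).sum())
        assert filter_expressed(m, 2).shape[0] == expected

    def test_nothing_left_raises(self):
        m = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
        with pytest.raises(ValueError, match="filter"):
            filter_expressed(m)


class TestNmf:
    def test_exact_rank_one_matrix_reconstructed(self):
        m = pd.DataFrame(np.ones((10, 8)))
        res = nmf_factorize(m, rank=1, n_restarts=3, seed=0)
        assert res.reconstruction_error <= 1e-6 * np.linalg.norm(m.to_numpy())

    def test_loss_history_non_increasing(self):
        m, _ = planted_block_matrix(seed=1)
        res = nmf_factorize(m, rank=4, n_restarts=2, seed=1)
        diffs = np.diff(res.loss_history)
        assert (diffs <= 1e-9 * res.loss_history[:-1] + 1e-12).all()

    def test_planted_blocks_recovered(self):
        hits = 0
        for seed in range(5):
            m, truth = planted_block_matrix(seed=seed)
            res = nmf_factorize(m, rank=4, n_restarts=8, seed=seed)
            hits += adjusted_rand_score(truth, res.assignments) == 1.0
        assert hits >= 4

    def test_column_permutation_equivariance(self):
        m, _ = planted_block_matrix(seed=2)
        res = nmf_factorize(m, rank=4, n_restarts=5, seed=7)
        perm = np.random.default_rng(0).permutation(m.shape[1])
        res_p = nmf_factorize(m.iloc[:, perm], rank=4, n_restarts=5, seed=7)
        # same partition of samples, up to component relabelling
        a = res.assignments[m.columns[perm]]
        b = res_p.assignments[m.columns[perm]]
        assert adjusted_rand_score(a, b) == 1.0

    def test_rank_too_large_rejected(self):
        m = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="rank"):
            nmf_factorize(m, rank=4)

    def test_nonnegative_factors_and_consensus_bounds(self):
        m, _ = planted_block_matrix(seed=3)
        res = nmf_factorize(m, rank=3, n_restarts=4, seed=3)
        assert (res.W.to_numpy() >= 0).all()
        assert (res.H.to_numpy() >= 0).all()
        C = res.consensus.to_numpy()
        assert ((C >= 0) & (C <= 1)).all()
        assert np.allclose(np.diag(C), 1.0)

    def test_matches_sklearn_reconstruction_quality(self):
        """Independent cross-check: our MU-NMF reaches the same loss scale as
        sklearn's MU solver on the same matrix."""
        from sklearn.decomposition import NMF

        m, _ = planted_block_matrix(seed=4)
        ours = nmf_factorize(m, rank=4, n_restarts=5, seed=0)
        sk = NMF(4, init="random", solver="mu", max_iter=2000, random_state=0)
        Wsk = sk.fit_transform(m.to_numpy())
        sk_err = np.linalg.norm(m.to_numpy() - Wsk @ sk.components_)
        assert ours.reconstruction_error <= sk_err * 1.05

    def test_top_loading_genes_sorted_descending(self):
        m, _ = planted_block_matrix(seed=5)
        res = nmf_factorize(m, rank=4, n_restarts=3, seed=5)
        top = top_loading_genes(res, 1, n=10)
        assert (np.diff(top.to_numpy()) <= 0).all()


class TestSelectRank:
    def test_planted_four_blocks_choose_rank_four(self):
        hits = 0
        for seed in range(5):
            m, _ = planted_block_matrix(seed=10 + seed)
            rank, profile = select_rank(m, range(2, 7), n_restarts=6, seed=seed)
            hits += rank == 4
        assert hits >= 4

    def test_rank_one_exact_matrix_fully_stable(self):
        m = pd.DataFrame(np.ones((12, 8)) * 3)
        rank, profile = select_rank(m, [1, 2, 3], n_restarts=4, seed=0)
        assert profile.loc[1, "cophenetic"] == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_returns_lowest_candidate_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(5, 1, size=(150, 20)).clip(0))
        with caplog.at_level("WARNING"):
            rank, _ = select_rank(m, range(2, 6), n_restarts=6, seed=0)
        assert rank == 2
        assert any("lowest candidate" in r.message for r in caplog.records)

    def test_single_candidate_rejected(self):
        m = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="two candidate"):
            select_rank(m, [2])


class TestHclustAndPca:
    def test_duplicated_groups_split_exactly_at_k2(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 1, size=(100, 1))
        b = rng.normal(5, 1, size=(100, 1))
        X = np.hstack([a, a, a, b, b, b]) + rng.normal(0, 1e-3, size=(100, 6))
        m = pd.DataFrame(X, columns=[f"s{j}" for j in range(6)])
        labels, Z = top_variable_hclust(m, 100, 2)
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_planted_two_groups_high_ari(self):
        config = CohortConfig(
            n_samples_per_subtype={"a": 10, "b": 10},
            n_background_genes=300,
            signature_spec=(
                SignatureSpec("mk", 50, {"a": 1, "b": -1}, 2.0),
            ),
            seed=0,
        )
        aris = []
        for seed in range(5):
            m, truth = generate_expression_cohort(
                CohortConfig(**{**config.__dict__, "seed": seed})
            )
            labels, _ = top_variable_hclust(m, 200, 2)
            aris.append(adjusted_rand_score(truth.to_series()[labels.index], labels))
        assert np.mean(aris) >= 0.9

    def test_constant_sample_error_names_sample(self):
        m = pd.DataFrame(
            np.random.default_rng(0).normal(size=(20, 3)),
            columns=["ok1", "flat", "ok2"],
        )
        m["flat"] = 2.0
        with pytest.raises(ValueError, match="flat"):
            top_variable_hclust(m, 20, 2)

    def test_newick_export_contains_all_leaves(self):
        m, _ = planted_block_matrix(seed=6)
        labels, Z = top_variable_hclust(m, 50, 4)
        newick = linkage_to_newick(Z, m.columns)
        assert newick.endswith(";")
        assert all(c in newick for c in m.columns)

    def test_pca_variance_fractions_non_increasing_and_bounded(self):
        m, _ = planted_block_matrix(seed=7)
        coords, var = pca_embed(m, 4)
        assert (np.diff(var) <= 1e-12).all()
        assert var.sum() <= 1.0 + 1e-9

    def test_duplicated_samples_identical_coordinates(self):
        m, _ = planted_block_matrix(seed=8)
        m["dup"] = m.iloc[:, 0]
        coords, _ = pca_embed(m, 2)
        np.testing.assert_allclose(
            coords.iloc[0].to_numpy(), coords.loc["dup"].to_numpy(), atol=1e-9
        )

    def test_two_group_cohort_separated_on_pc1(self):
        config = CohortConfig(
            n_samples_per_subtype={"a": 12, "b": 12},
            n_background_genes=200,
            signature_spec=(SignatureSpec("mk", 60, {"a": 1, "b": -1}, 2.0),),
            seed=4,
        )
        m, truth = generate_expression_cohort(config)
        coords, _ = pca_embed(m, 2)
        g = (truth.to_series()[coords.index] == "a").astype(float)
        r = np.corrcoef(coords["PC1"], g)[0, 1]
        assert abs(r) >= 0.8

    def test_too_many_components_rejected(self):
        m, _ = planted_block_matrix(seed=9)
        with pytest.raises(ValueError, match="components"):
            pca_embed(m, m.shape[1] + 1)
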