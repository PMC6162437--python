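"""ssGSEA running-sum scoring and the two-group permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcinvasion import (
    gsea_two_group,
    rank_transform,
    ssgsea_matrix,
    ssgsea_score,
)
from crcinvasion.signatures import GeneSet, SignatureCollection


def brute_force_es(ranks: dict, subset: set, weight: float) -> float:
    """Independent literal enumeration of the running sum (the oracle)."""
    genes = sorted(ranks, key=lambda g: -ranks[g])
    denom = sum(ranks[g] ** weight for g in genes if g in subset)
    n_miss = sum(1 for g in genes if g not in subset)
    es = cum_hit = cum_miss = 0.0
    for g in genes:
        if g in subset:
            cum_hit += ranks[g] ** weight / denom
        else:
            cum_miss += 1.0 / n_miss
        es += cum_hit - cum_miss
    return es


class TestRankTransform:
    def test_strictly_ordered_sample(self):
        m = pd.DataFrame({"s": [4.0, 3.0, 2.0, 1.0]}, index=list("ABCD"))
        ranks = rank_transform(m)
        assert list(ranks["s"]) == [4, 3, 2, 1]

    def test_monotone_transform_invariance(self, small_matrix):
        r1 = rank_transform(small_matrix)
        r2 = rank_transform(np.exp(small_matrix / 3) + 7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_ties_resolved_by_gene_id_deterministically(self):
        m = pd.DataFrame({"s": [1.0, 1.0, 0.0]}, index=["B", "A", "C"])
        for _ in range(3):
            ranks = rank_transform(m)
            # equal values: lexicographically smaller id gets the lower rank
            assert ranks.loc["A", "s"] == 2
            assert ranks.loc["B", "s"] == 3
            assert ranks.loc["C", "s"] == 1

    def test_all_ranks_distinct_even_with_constant_sample(self):
        m = pd.DataFrame({"s": [2.0] * 5}, index=list("EDCBA"))
        ranks = rank_transform(m)
        assert sorted(ranks["s"]) == [1, 2, 3, 4, 5]


class TestSsgseaScore:
    def setup_method(self):
        self.ranks = pd.Series([4, 3, 2, 1], index=list("ABCD"))

    def test_hand_enumerated_alternating_set(self):
        assert ssgsea_score(self.ranks, {"A", "C"}, 0.0) == pytest.approx(1.0)

    def test_complement_antisymmetry_at_weight_zero(self):
        assert ssgsea_score(self.ranks, {"B", "D"}, 0.0) == pytest.approx(-1.0)

    def test_whole_universe_set_rejected(self):
        with pytest.raises(ValueError, match="entire"):
            ssgsea_score(self.ranks, set("ABCD"), 0.25)

    def test_single_gene_set_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ssgsea_score(self.ranks, {"A"}, 0.25)

    def test_matches_brute_force_on_random_universe(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i:02d}" for i in range(30)]
        values = pd.Series(rng.normal(size=30), index=genes)
        ranks = rank_transform(values.to_frame("s"))["s"]
        subset = set(rng.choice(genes, size=8, replace=False))
        expected = brute_force_es(dict(ranks), subset, 0.25)
        assert ssgsea_score(ranks, subset, 0.25) == pytest.approx(expected, abs=1e-9)

    def test_exhaustive_small_universe_equivalence(self):
        """Every 2-4 gene subset of a 6-gene universe matches the oracle."""
        rng = np.random.default_rng(2)
        genes = list("ABCDEF")
        ranks = rank_transform(
            pd.DataFrame(rng.normal(size=(6, 3)), index=genes)
        )
        for k in (2, 3, 4):
            for subset in itertools.combinations(genes, k):
                for col in ranks:
                    got = ssgsea_score(ranks[col], set(subset), 0.25)
                    want = brute_force_es(dict(ranks[col]), set(subset), 0.25)
                    assert got == pytest.approx(want, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_leaves_score_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(size=(12, 1)), index=[f"g{i}" for i in range(12)])
        subset = set(rng.choice(m.index, size=4, replace=False))
        r1 = rank_transform(m).iloc[:, 0]
        r2 = rank_transform(m * 3 + 10).iloc[:, 0]
        assert ssgsea_score(r1, subset, 0.25) == ssgsea_score(r2, subset, 0.25)


class TestSsgseaMatrix:
    def collection(self):
        coll = SignatureCollection()
        coll.add(GeneSet("UP", "", ("G00", "G01", "G02")))
        coll.add(GeneSet("DOWN", "", ("G07", "G08", "G09")))
        return coll

    def matrix(self, n_samples=4, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(5, 1, size=(10, n_samples)),
            index=[f"G{i:02d}" for i in range(10)],
            columns=[f"S{j}" for j in range(n_samples)],
        )

    def test_composition_matches_per_sample_scores(self):
        m = self.matrix(1)
        esm = ssgsea_matrix(m, self.collection(), 0.25)
        ranks = rank_transform(m).iloc[:, 0]
        assert esm.loc["UP", "S0"] == pytest.approx(
            ssgsea_score(ranks, {"G00", "G01", "G02"}, 0.25)
        )

    def test_duplicated_sample_gives_identical_columns(self):
        m = self.matrix(3)
        m["S_dup"] = m["S0"]
        esm = ssgsea_matrix(m, self.collection())
        pd.testing.assert_series_equal(
            esm["S0"], esm["S_dup"], check_names=False
        )

    def test_normalization_divides_by_global_range(self):
        m = self.matrix(4)
        raw = ssgsea_matrix(m, self.collection(), normalize=False)
        norm = ssgsea_matrix(m, self.collection(), normalize=True)
        span = raw.to_numpy().max() - raw.to_numpy().min()
        pd.testing.assert_frame_equal(norm, raw / span)

    def test_unusable_sets_omitted_with_warning(self, caplog):
        coll = self.collection()
        coll.add(GeneSet("ABSENT", "", ("Z1", "Z2", "Z3")))
        with caplog.at_level("WARNING"):
            esm = ssgsea_matrix(self.matrix(), coll)
        assert "ABSENT" not in esm.index
        assert set(esm.index) == {"UP", "DOWN"}


class TestGseaTwoGroup:
    def planted_matrix(self, shift, seed=0, n_per=10, n_genes=60, set_size=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(5, 1, size=(n_genes, 2 * n_per))
        X[:set_size, :n_per] += shift
        m = pd.DataFrame(
            X,
            index=[f"G{i:03d}" for i in range(n_genes)],
            columns=[f"S{j:02d}" for j in range(2 * n_per)],
        )
        labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=m.columns)
        return m, labels, [f"G{i:03d}" for i in range(set_size)]

    def test_extreme_observed_statistic_gives_exact_minimum_p(self):
        """With n_perm = 19 and the observed stat most extreme, p = 1/20."""
        m, labels, gene_set = self.planted_matrix(5.0, seed=1)
        res = gsea_two_group(m, labels, gene_set, n_perm=19, seed=0)
        assert res.p_value == pytest.approx(1 / 20)

    def test_p_granularity_floor(self):
        m, labels, gene_set = self.planted_matrix(0.0, seed=2)
        res = gsea_two_group(m, labels, gene_set, n_perm=49, seed=0)
        assert res.p_value >= 1 / 50
        assert res.p_value <= 1.0

    def test_planted_shift_detected_with_small_p(self):
        m, labels, gene_set = self.planted_matrix(2.0, seed=3)
        res = gsea_two_group(m, labels, gene_set, n_perm=499, seed=0)
        assert res.p_value <= 0.01
        assert res.es > 0

    def test_phenotype_scheme_used_for_large_groups(self):
        m, labels, gene_set = self.planted_matrix(1.0, seed=4)
        res = gsea_two_group(m, labels, gene_set, n_perm=19, seed=0)
        assert res.permutation_scheme == "phenotype"

    def test_gene_set_scheme_used_for_tiny_groups(self):
        m, labels, gene_set = self.planted_matrix(1.0, seed=5, n_per=4)
        res = gsea_two_group(m, labels, gene_set, n_perm=19, seed=0)
        assert res.permutation_scheme == "gene_set"

    def test_empty_group_rejected(self):
        m, labels, gene_set = self.planted_matrix(1.0)
        labels[:] = "a"
        with pytest.raises(ValueError, match="two groups"):
            gsea_two_group(m, labels, gene_set, n_perm=19)

    def test_null_type_one_error_near_nominal(self):
        """Quick null calibration: 60 sims at alpha 0.05 (full 500 in the
        acceptance suite)."""
        rng = np.random.default_rng(6)
        hits = 0
        for sim in range(60):
            X = rng.normal(5, 1, size=(40, 16))
            m = pd.DataFrame(
                X,
                index=[f"G{i:02d}" for i in range(40)],
                columns=[f"S{j:02d}" for j in range(16)],
            )
            labels = pd.Series(["a"] * 8 + ["b"] * 8, index=m.columns)
            res = gsea_two_group(m, labels, [f"G{i:02d}" for i in range(8)],
                                 n_perm=99, seed=sim)
            hits += res.p_value < 0.05
        assert hits <= 9  # binomial(60, 0.05) upper tail
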