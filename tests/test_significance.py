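import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drugsimnet.de import DEProfile
from drugsimnet.propagation import CentralityVector
from drugsimnet.significance import (
    NullScores,
    bh_fdr,
    bootstrap_null,
    empirical_pvalues,
    rank_drugs,
)


def bh_step_up_oracle(p):
    """Reference BH: sort, p(i) * m / i, cumulative min from the largest."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def centrality(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"D{i}" for i in range(len(values))]
    return CentralityVector(drug_ids=list(ids), v=values, iterations=1, converged=True)


class TestEmpiricalPValues:
    def test_direct_count(self):
        null = NullScores(drug_ids=["D0"], scores=np.linspace(0, 1, 1000)[:, None])
        obs = centrality([0.99], ["D0"])
        p = empirical_pvalues(obs, null)
        assert p["D0"] == pytest.approx(10 / 1000)

    def test_all_nulls_below_gives_zero(self):
        null = NullScores(drug_ids=["D0"], scores=np.zeros((50, 1)))
        assert empirical_pvalues(centrality([0.5], ["D0"]), null)["D0"] == 0.0

    def test_ties_count_inclusively(self):
        null = NullScores(drug_ids=["D0"], scores=np.full((20, 1), 0.3))
        assert empirical_pvalues(centrality([0.3], ["D0"]), null)["D0"] == 1.0

    def test_pseudocount_variant(self):
        null = NullScores(drug_ids=["D0"], scores=np.zeros((99, 1)))
        p = empirical_pvalues(centrality([0.5], ["D0"]), null, pseudocount=True)
        assert p["D0"] == pytest.approx(1 / 100)

    def test_matches_naive_counting_loop(self):
        rng = np.random.default_rng(0)
        scores = rng.random((200, 12))
        obs = rng.random(12)
        null = NullScores(drug_ids=[f"D{i}" for i in range(12)], scores=scores)
        p = empirical_pvalues(centrality(obs), null)
        for i in range(12):
            naive = sum(scores[k, i] >= obs[i] for k in range(200)) / 200
            assert p.iloc[i] == pytest.approx(naive)

    def test_misaligned_ids_rejected(self):
        null = NullScores(drug_ids=["D0"], scores=np.zeros((5, 1)))
        with pytest.raises(ValueError, match="DX"):
            empirical_pvalues(centrality([0.1], ["DX"]), null)


class TestBHFDR:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_all_equal_p_stay_equal(self):
        out = bh_fdr(np.full(7, 0.2))
        np.testing.assert_allclose(out, 0.2)

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(np.array(p)), bh_step_up_oracle(p), atol=1e-12)

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(15)
            q = p.copy()
            i = rng.integers(15)
            q[i] = p[i] * rng.random()  # decrease one p-value
            assert (bh_fdr(q) <= bh_fdr(p) + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]))

    def test_series_index_preserved(self):
        s = pd.Series([0.04, 0.01], index=["b", "a"])
        out = bh_fdr(s)
        assert list(out.index) == ["b", "a"]


class TestBootstrapNull:
    def test_same_seed_reproduces_replicates(self, small_bundle):
        from drugsimnet.de import compute_de_scores, zscore_normalize

        de = compute_de_scores(zscore_normalize(small_bundle.expression))
        kw = dict(B=3, seed=5)
        n1 = bootstrap_null(small_bundle.catalog, small_bundle.sets, de, **kw)
        n2 = bootstrap_null(small_bundle.catalog, small_bundle.sets, de, **kw)
        np.testing.assert_array_equal(n1.scores, n2.scores)

    def test_different_seeds_differ(self, small_bundle):
        from drugsimnet.de import compute_de_scores, zscore_normalize

        de = compute_de_scores(zscore_normalize(small_bundle.expression))
        n1 = bootstrap_null(small_bundle.catalog, small_bundle.sets, de, B=2, seed=1)
        n2 = bootstrap_null(small_bundle.catalog, small_bundle.sets, de, B=2, seed=2)
        assert not np.array_equal(n1.scores, n2.scores)

    def test_constant_de_pool_reproduces_observed(self, small_bundle):
        from drugsimnet.network import BipartiteStructure
        from drugsimnet.significance import _replicate_centrality

        genes = small_bundle.expression.gene_ids
        const = DEProfile(
            table=pd.DataFrame({"p": 0.5, "z": 1.0, "de_score": 1.0}, index=genes)
        )
        null = bootstrap_null(
            small_bundle.catalog, small_bundle.sets, const, B=4, seed=3
        )
        structure = BipartiteStructure.build(
            small_bundle.catalog, small_bundle.sets, genes
        )
        observed = _replicate_centrality(
            structure, np.ones(len(genes)), r=0.9, tol=1e-10, max_iter=10000
        )
        for row in null.scores:
            np.testing.assert_allclose(row, observed, atol=1e-12)

    def test_zero_replicates_rejected(self, small_bundle):
        from drugsimnet.de import compute_de_scores, zscore_normalize

        de = compute_de_scores(zscore_normalize(small_bundle.expression))
        with pytest.raises(ValueError):
            bootstrap_null(small_bundle.catalog, small_bundle.sets, de, B=0)

    def test_rows_are_probability_vectors(self, small_bundle):
        from drugsimnet.de import compute_de_scores, zscore_normalize

        de = compute_de_scores(zscore_normalize(small_bundle.expression))
        null = bootstrap_null(
            small_bundle.catalog, small_bundle.sets, de, B=5, seed=9
        )
        sums = null.scores.sum(axis=1)
        assert ((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0)).all()


class TestRankDrugs:
    def test_fdr_exactly_at_threshold_is_not_candidate(self):
        cv = centrality([0.5, 0.3], ["Da", "Db"])
        p = pd.Series([0.05, 0.2], index=["Da", "Db"])
        fdr = pd.Series([0.1, 0.2], index=["Da", "Db"])
        table = rank_drugs(cv, p, fdr, threshold=0.1)
        assert not table.set_index("drug_id")["candidate"]["Da"]

    def test_highest_centrality_gets_rank_one(self):
        cv = centrality([0.2, 0.7, 0.1])
        table = rank_drugs(cv)
        assert table.iloc[0]["drug_id"] == "D1"
        assert table.iloc[0]["rank"] == 1

    def test_ties_ranked_in_drug_id_order(self):
        cv = centrality([0.3, 0.3, 0.5], ["Db", "Da", "Dc"])
        table = rank_drugs(cv)
        assert list(table["drug_id"]) == ["Dc", "Da", "Db"]

    def test_isolated_drugs_appended_with_p_one(self):
        cv = centrality([0.6, 0.4], ["Da", "Db"])
        p = pd.Series([0.01, 0.3], index=["Da", "Db"])
        table = rank_drugs(cv, p, bh_fdr(p), isolated=["Dz"])
        row = table.set_index("drug_id").loc["Dz"]
        assert row["centrality_score"] == 0.0
        assert row["p_value"] == 1.0
        assert row["rank"] == 3

    def test_length_mismatch_rejected(self):
        cv = centrality([0.6, 0.4], ["Da", "Db"])
        p = pd.Series([0.01], index=["Da"])
        with pytest.raises(ValueError):
            rank_drugs(cv, p)
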