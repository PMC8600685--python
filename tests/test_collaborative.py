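import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trimda.collaborative import (
    CollaborativeFilter,
    RecommendationSet,
    cooccurrence_similarity,
    densify,
    recommend_edges,
    recommender_matrix,
    update_graph,
)

from conftest import graph_from_matrices, random_graph

SQRT2 = np.sqrt(2.0)


class TestCooccurrenceSimilarity:
    def test_shared_neighbour_cosine(self, toy_graph):
        # N(m0) = {l0, d0}, N(m1) = {l0}
        sim = cooccurrence_similarity(toy_graph)
        assert sim.R_nor[0, 1] == pytest.approx(1 / SQRT2, abs=1e-12)
        assert np.array_equal(sim.R, np.ones((2, 2), dtype=int))

    def test_unit_diagonal_for_connected_mirnas(self, rng):
        g = random_graph(rng, 10, 6, 5, p=0.4)
        r = cooccurrence_similarity(g).R_nor
        connected = g.splice_mld().sum(axis=1) > 0
        assert np.allclose(np.diag(r)[connected], 1.0)
        assert np.all(np.diag(r)[~connected] == 0.0)

    def test_disjoint_neighbourhoods_give_zero(self):
        g = graph_from_matrices([[1, 0], [0, 1]], [[0, 0], [0, 0]], [[0, 0], [0, 0]])
        sim = cooccurrence_similarity(g)
        assert sim.R_nor[0, 1] == 0.0 and sim.R[0, 1] == 0

    def test_all_zero_graph_warns_and_returns_zeros(self, caplog):
        g = graph_from_matrices([[0]], [[0]], [[0]])
        with caplog.at_level("WARNING"):
            sim = cooccurrence_similarity(g)
        assert sim.R_nor.sum() == 0
        assert any("all-zero" in r.message for r in caplog.records)

    def test_rejects_updated_graph(self, rng):
        g = random_graph(rng, 4, 3, 2, stage="updated")
        with pytest.raises(ValueError, match="initial"):
            cooccurrence_similarity(g)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        md=arrays(np.int8, (6, 4), elements=st.integers(0, 1)),
        ml=arrays(np.int8, (6, 3), elements=st.integers(0, 1)),
    )
    def test_symmetry_range_and_support(self, md, ml):
        """R_nor is symmetric, lies in [0,1], and is supported exactly on R."""
        g = graph_from_matrices(md, ml, np.zeros((4, 3), dtype=np.int8))
        sim = cooccurrence_similarity(g)
        assert np.allclose(sim.R_nor, sim.R_nor.T)
        assert (sim.R_nor >= 0).all() and (sim.R_nor <= 1 + 1e-12).all()
        assert np.array_equal(sim.R_nor > 0, sim.R.astype(bool))

    def test_equals_cosine_of_spliced_rows(self, rng):
        from sklearn.metrics.pairwise import cosine_similarity

        g = random_graph(rng, 15, 10, 8, p=0.3)
        mld = g.splice_mld().astype(float)
        keep = mld.sum(axis=1) > 0
        ours = cooccurrence_similarity(g).R_nor
        ref = cosine_similarity(mld)
        assert np.allclose(ours[np.ix_(keep, keep)], ref[np.ix_(keep, keep)], atol=1e-12)


class TestRecommenderMatrix:
    def test_identity_similarity_returns_input(self, rng):
        g = random_graph(rng, 5, 4, 3)
        sim = cooccurrence_similarity(g)
        sim.R_nor = np.eye(5)
        rec = recommender_matrix(sim, g)
        assert np.array_equal(rec.A_u_MLD, g.splice_mld())

    def test_two_mirna_hand_product(self):
        # A0_MLD = [[1,1],[1,0]] -> A_u = [[1+1/sqrt2, 1], [1+1/sqrt2, 1/sqrt2]]
        g = graph_from_matrices([[1], [0]], [[1], [1]], [[1]])
        rec = recommender_matrix(cooccurrence_similarity(g), g)
        expected = np.array([[1 + 1 / SQRT2, 1], [1 + 1 / SQRT2, 1 / SQRT2]])
        assert np.allclose(rec.A_u_MLD, expected, atol=1e-12)
        assert np.allclose(rec.column_avgs, expected.sum(axis=0) / 2, atol=1e-12)

    def test_column_avgs_nonnegative_zero_only_for_zero_columns(self, rng):
        g = random_graph(rng, 8, 5, 4, p=0.25)
        rec = recommender_matrix(cooccurrence_similarity(g), g)
        assert (rec.column_avgs >= 0).all()
        zero_cols = rec.A_u_MLD.sum(axis=0) == 0
        assert np.array_equal(rec.column_avgs == 0, zero_cols)

    def test_nonzero_rows_denominator(self):
        g = graph_from_matrices([[1], [0]], [[1], [1]], [[1]])
        sim = cooccurrence_similarity(g)
        rec = recommender_matrix(sim, g, p_denominator="nonzero_rows")
        # disease column has values (1, 1/sqrt2): both nonzero -> mean over 2
        assert rec.column_avgs[1] == pytest.approx((1 + 1 / SQRT2) / 2)

    def test_invalid_denominator(self, toy_graph):
        with pytest.raises(ValueError, match="p_denominator"):
            recommender_matrix(cooccurrence_similarity(toy_graph), toy_graph, "median")


class TestRecommendEdges:
    def test_threshold_and_known_exclusion(self, toy_graph):
        # disease column of A_u is (1, 1/sqrt2), P = (1 + 1/sqrt2)/2 ~ 0.854:
        # m0 already known, m1 below P -> only the lncRNA column can recommend,
        # and there both entries are known -> no edges at all
        rec = recommender_matrix(cooccurrence_similarity(toy_graph), toy_graph)
        out = recommend_edges(rec, toy_graph)
        assert len(out) == 0

    def test_single_recommendation_above_p(self):
        # three miRNAs sharing lncRNA l0; only m0 linked to d0
        g = graph_from_matrices(
            [[1], [0], [0]], [[1, 1], [1, 1], [1, 0]], [[1, 0]]
        )
        rec = recommender_matrix(cooccurrence_similarity(g), g)
        out = recommend_edges(rec, g)
        disease_recs = [e for e in out.edges if e[2] == "disease"]
        # m1 has the same lncRNA profile as m0 -> recommended for d0; m2 weaker
        assert ("m1", "d0", "disease") in [(m, t, r) for m, t, r, _ in disease_recs]
        col = rec.A_u_MLD[:, 2]
        p = rec.column_avgs[2]
        for m, t, r, score in disease_recs:
            k = g.mirnas.position(m)
            assert score > p and g.A_MD[k, 0] == 0

    def test_column_without_known_edges_gets_no_recommendations(self):
        g = graph_from_matrices(
            [[1, 0], [1, 0]], [[1], [1]], [[1], [0]]
        )
        rec = recommender_matrix(cooccurrence_similarity(g), g)
        out = recommend_edges(rec, g)
        assert all(not (r == "disease" and t == "d1") for _, t, r, _ in out.edges)

    def test_no_edge_duplicates_known_entries(self, rng):
        g = random_graph(rng, 10, 7, 5, p=0.3)
        rec = recommender_matrix(cooccurrence_similarity(g), g)
        for m, t, role, _ in recommend_edges(rec, g).edges:
            k = g.mirnas.position(m)
            if role == "disease":
                assert g.A_MD[k, g.diseases.position(t)] == 0
            else:
                assert g.A_ML[k, g.lncrnas.position(t)] == 0


class TestUpdateGraph:
    def test_empty_recommendations_is_noop_with_stage_flip(self, rng):
        g = random_graph(rng, 6, 4, 3)
        gu = update_graph(g, RecommendationSet(edges=[]))
        assert gu.stage == "updated"
        assert np.array_equal(gu.A_MD, g.A_MD) and np.array_equal(gu.A_ML, g.A_ML)

    def test_never_deletes_an_edge_and_dl_unchanged(self, rng):
        for seed in range(5):
            g = random_graph(np.random.default_rng(seed), 12, 8, 6, p=0.25)
            gu = densify(g)
            assert (gu.A_MD >= g.A_MD).all() and (gu.A_ML >= g.A_ML).all()
            assert np.array_equal(gu.A_DL, g.A_DL)
            assert gu.A_MD.sum() + (gu.A_MD == 0).sum() == g.n_m * g.n_d

    def test_deterministic(self, rng):
        g = random_graph(rng, 10, 6, 5, p=0.3)
        g1, g2 = densify(g), densify(g)
        assert np.array_equal(g1.A_MD, g2.A_MD) and np.array_equal(g1.A_ML, g2.A_ML)


class TestCollaborativeFilterEstimator:
    def test_fit_exposes_stages_and_transform(self, rng):
        g = random_graph(rng, 10, 6, 5, p=0.3)
        cf = CollaborativeFilter().fit(g)
        assert cf.graph_.stage == "updated"
        assert cf.similarity_.R_nor.shape == (10, 10)
        assert np.array_equal(cf.transform(g).A_MD, cf.graph_.A_MD)
        assert np.array_equal(cf.fit_transform(g).A_MD, cf.graph_.A_MD)

    def test_sklearn_params_round_trip(self):
        cf = CollaborativeFilter(p_denominator="nonzero_rows")
        assert cf.get_params() == {"p_denominator": "nonzero_rows"}
        cf.set_params(p_denominator="all_rows")
        assert cf.p_denominator == "all_rows"
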