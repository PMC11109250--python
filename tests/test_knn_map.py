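import numpy as np
import pandas as pd
import pytest

from _oracles import knn_bruteforce, similarity_recount
from homomap import (
    CrossSpeciesGraph,
    JointEmbedding,
    ResolvedMap,
    build_knn,
    driving_genes,
    joint_embed,
    read_graph_tsv,
    reciprocal_top_hits,
    score_permutation_test,
    similarity_scores,
    simulate_bipartite_knn,
    write_graph_tsv,
)
from test_markers import marker_set_from
from tests_common import dataset_from_dense


def embedding_from(coords, species):
    coords = np.asarray(coords, dtype=float)
    return JointEmbedding(
        coords=coords,
        species=np.asarray(species, dtype=object),
        node_ids=[f"n{i}" for i in range(len(coords))],
        labels=np.array(["t"] * len(coords), dtype=object),
    )


class TestJointEmbed:
    def test_relabeled_copy_gets_identical_coordinates(self, species_pair, small_cfg):
        ds_a = species_pair[0]
        from dataclasses import replace

        renamed = replace(
            ds_a,
            species_tag="bcopy",
            gene_ids=[f"H_{g}" for g in ds_a.gene_ids],
            cell_ids=[f"copy_{c}" for c in ds_a.cell_ids],
        )
        mapping = ResolvedMap.from_dict({g: f"H_{g}" for g in ds_a.gene_ids})
        emb = joint_embed(ds_a, renamed, mapping, n_dims=10)
        n = ds_a.n_cells
        assert np.allclose(emb.coords[:n], emb.coords[n:], atol=1e-8)

    def test_one_dimension_separates_two_types(self):
        rng = np.random.default_rng(0)
        dense = np.zeros((20, 40), dtype=int)
        dense[:10, :20] = rng.poisson(50, (10, 20))
        dense[10:, 20:] = rng.poisson(50, (10, 20))
        ds_a = dataset_from_dense(dense, ["T0"] * 20 + ["T1"] * 20, species_tag="a")
        ds_b = dataset_from_dense(dense, ["T0"] * 20 + ["T1"] * 20, species_tag="b")
        emb = joint_embed(ds_a, ds_b, None, n_dims=1)
        signs = np.sign(emb.coords[:40, 0])
        assert len(set(signs[:20])) == 1
        assert len(set(signs[20:40])) == 1
        assert signs[0] != signs[20]

    def test_all_zero_weights_rejected(self, species_pair):
        ds_a, ds_b, truth = species_pair
        mapping = ResolvedMap.from_dict(truth.true_ortholog_map)
        weights = {(g, s): 0.0 for g, s in truth.true_ortholog_map.items()}
        with pytest.raises(ValueError):
            joint_embed(ds_a, ds_b, mapping, weights=weights, n_dims=5)

    def test_deterministic(self, species_pair):
        ds_a, ds_b, truth = species_pair
        mapping = ResolvedMap.from_dict(truth.true_ortholog_map)
        e1 = joint_embed(ds_a, ds_b, mapping, n_dims=8)
        e2 = joint_embed(ds_a, ds_b, mapping, n_dims=8)
        assert np.array_equal(e1.coords, e2.coords)


class TestBuildKnn:
    def test_collinear_points(self):
        emb = embedding_from([[0.0], [1.0], [3.0]], ["a", "a", "b"])
        g = build_knn(emb, k=1)
        assert g.neighbors[1, 0] == 0  # middle point's nearer endpoint

    def test_k_equals_n_minus_one(self):
        emb = embedding_from(np.arange(5.0)[:, None], ["a"] * 3 + ["b"] * 2)
        g = build_knn(emb, k=4)
        for i in range(5):
            assert set(g.neighbors[i]) == set(range(5)) - {i}

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(3):
            n = int(rng.integers(20, 60))
            coords = rng.random((n, 3))
            emb = embedding_from(coords, ["a"] * (n // 2) + ["b"] * (n - n // 2))
            k = int(rng.integers(1, 6))
            g = build_knn(emb, k=k)
            assert np.array_equal(g.neighbors, knn_bruteforce(coords, k))

    def test_k_too_large_rejected(self):
        emb = embedding_from([[0.0], [1.0]], ["a", "b"])
        with pytest.raises(ValueError):
            build_knn(emb, k=2)


class TestSimilarityScores:
    def test_perfect_preference_graph(self):
        labels = np.repeat(["x", "y"], 8)
        g, labs = simulate_bipartite_knn(16, 16, labels, labels, k=5,
                                         within_type_bias=1.0, seed=1)
        S = similarity_scores(g, labs)
        assert np.allclose(np.diag(S), 5.0)
        assert np.allclose(S.to_numpy()[~np.eye(2, dtype=bool)], 0.0)

    def test_no_cross_edges_gives_zero_matrix(self):
        # neighbors all within species
        neighbors = np.array([[1], [0], [3], [2]])
        g = CrossSpeciesGraph(
            node_ids=["a0", "a1", "b0", "b1"],
            species=np.array(["a", "a", "b", "b"], dtype=object),
            neighbors=neighbors,
            k=1,
        )
        S = similarity_scores(g, np.array(["t", "u", "t", "u"], dtype=object))
        assert (S.to_numpy() == 0).all()

    def test_matches_double_loop_recount(self, rng):
        labels_a = rng.choice(["t1", "t2", "t3"], size=40)
        labels_b = rng.choice(["t1", "t2"], size=30)
        g, labs = simulate_bipartite_knn(40, 30, labels_a, labels_b, k=4,
                                         within_type_bias=0.6, seed=7)
        S = similarity_scores(g, labs)
        for ta in S.index:
            for tb in S.columns:
                ref = similarity_recount(
                    g.neighbors, g.species, labs, ta, tb, "a", "b"
                )
                assert S.loc[ta, tb] == ref

    def test_every_cross_neighbor_counted_exactly_once(self, rng):
        labels_a = rng.choice(["t1", "t2"], size=25)
        labels_b = rng.choice(["u1", "u2", "u3"], size=25)
        g, labs = simulate_bipartite_knn(25, 25, labels_a, labels_b, k=3,
                                         within_type_bias=0.0, seed=8)
        S = similarity_scores(g, labs)
        # reweight score cells back to raw counts; total = all cross edges
        n_a = {t: (labs[:25] == t).sum() for t in S.index}
        n_b = {t: (labs[25:] == t).sum() for t in S.columns}
        total = sum(
            S.loc[ta, tb] * (n_a[ta] + n_b[tb]) for ta in S.index for tb in S.columns
        )
        assert np.isclose(total, 2 * 25 * 3)  # all edges are cross-species here


class TestScorePermutation:
    def test_uniform_labels_give_q_one(self):
        labels = np.array(["t"] * 10)
        g, labs = simulate_bipartite_knn(10, 10, labels, labels, k=3,
                                         within_type_bias=0.0, seed=0)
        q = score_permutation_test(g, labs, n_perm=20, seed=1)
        assert (q.to_numpy() == 1.0).all()

    def test_planted_preference_reaches_q_zero(self):
        labels = np.repeat(["x", "y", "z"], 15)
        g, labs = simulate_bipartite_knn(45, 45, labels, labels, k=5,
                                         within_type_bias=1.0, seed=2)
        q = score_permutation_test(g, labs, n_perm=200, seed=3)
        assert all(q.loc[t, t] == 0.0 for t in ("x", "y", "z"))

    def test_q_invariant_to_type_renaming(self):
        labels = np.repeat(["x", "y"], 12)
        g, labs = simulate_bipartite_knn(24, 24, labels, labels, k=4,
                                         within_type_bias=0.7, seed=4)
        q1 = score_permutation_test(g, labs, n_perm=100, seed=5)
        renamed = np.array([{"x": "u", "y": "v"}[t] for t in labs], dtype=object)
        q2 = score_permutation_test(g, renamed, n_perm=100, seed=5)
        assert np.array_equal(q1.to_numpy(), q2.to_numpy())

    def test_pooled_row_null_is_no_less_conservative(self):
        labels = np.repeat(["x", "y"], 12)
        g, labs = simulate_bipartite_knn(24, 24, labels, labels, k=4,
                                         within_type_bias=0.9, seed=6)
        q_pair = score_permutation_test(g, labs, n_perm=100, seed=7)
        q_row = score_permutation_test(g, labs, n_perm=100, seed=7, null="pooled-row")
        assert (q_row.to_numpy() >= q_pair.to_numpy() - 1e-12).all()


class TestReciprocalTopHits:
    def test_identity_dominant_matrix(self):
        S = pd.DataFrame(np.eye(3) + 0.1, index=list("abc"), columns=list("xyz"))
        flags = reciprocal_top_hits(S)
        assert np.array_equal(flags.to_numpy(), np.eye(3, dtype=bool))

    def test_constant_matrix_has_no_flags(self):
        S = pd.DataFrame(np.ones((2, 2)))
        assert not reciprocal_top_hits(S).to_numpy().any()

    def test_matches_bruteforce_argmax(self, rng):
        S = pd.DataFrame(rng.random((6, 5)))
        flags = reciprocal_top_hits(S).to_numpy()
        M = S.to_numpy()
        for i in range(6):
            for j in range(5):
                expect = (
                    M[i, j] > np.delete(M[i], j).max()
                    and M[i, j] > np.delete(M[:, j], i).max()
                )
                assert flags[i, j] == expect


class TestDrivingGenes:
    def setup_profiles(self, vals_a, vals_b):
        genes = [f"g{i}" for i in range(len(vals_a))]
        pa = pd.DataFrame([vals_a], index=["T"], columns=genes)
        pb = pd.DataFrame([vals_b], index=["U"], columns=genes)
        ms = marker_set_from({"T": {g: 1.0 for g in genes}})
        mu = marker_set_from({"U": {g: 1.0 for g in genes}})
        return pa, pb, ms, mu

    def test_identical_profiles_all_qualify(self, rng):
        vals = list(rng.permutation(10).astype(float))
        pa, pb, ms, mu = self.setup_profiles(vals, vals)
        out = driving_genes(("T", "U"), ms, mu, pa, pb, None)
        assert len(out) == 10

    def test_anticorrelated_profiles_yield_nothing(self, rng):
        vals = list(rng.permutation(10).astype(float))
        rev = [-v for v in vals]
        pa, pb, ms, mu = self.setup_profiles(vals, rev)
        assert driving_genes(("T", "U"), ms, mu, pa, pb, None) == []

    # 20-gene toys with moderate overall rho and clearly discordant genes;
    # the rank-product sign and the leave-one-out delta-rho sign agree only
    # where contributions are decisive (near-zero contributions have an
    # essentially arbitrary leave-one-out sign at very high rho)
    @pytest.mark.parametrize(
        "swaps",
        [
            [(4, 19.5), (9, 0.5), (14, 20.5), (17, 1.5)],
            [(0, 20.4), (9, 0.6), (19, 0.2), (4, 16.8), (15, 3.3)],
        ],
    )
    def test_agrees_with_leave_one_out_oracle(self, swaps):
        import scipy.stats

        vals_a = np.arange(1.0, 21.0)
        vals_b = vals_a.copy()
        for i, newv in swaps:
            vals_b[i] = newv
        pa, pb, ms, mu = self.setup_profiles(list(vals_a), list(vals_b))
        out = {ga for ga, _, _ in driving_genes(("T", "U"), ms, mu, pa, pb, None)}
        rho_full = scipy.stats.spearmanr(vals_a, vals_b).statistic
        agree = 0
        for i in range(20):
            rho_loo = scipy.stats.spearmanr(
                np.delete(vals_a, i), np.delete(vals_b, i)
            ).statistic
            agree += (rho_full > rho_loo) == (f"g{i}" in out)
        assert agree / 20 >= 0.9

    def test_empty_deg_space_rejected(self):
        ms = marker_set_from({"T": {"a": 1.0}})
        mu = marker_set_from({"U": {"b": 1.0}})
        pa = pd.DataFrame([[1.0]], index=["T"], columns=["a"])
        pb = pd.DataFrame([[1.0]], index=["U"], columns=["b"])
        with pytest.raises(ValueError):
            driving_genes(("T", "U"), ms, mu, pa, pb,
                          ResolvedMap.from_dict({"a": "zz"}))


class TestGraphInterchange:
    def test_tsv_roundtrip(self, tmp_path, rng):
        labels = np.repeat(["x", "y"], 6)
        g, labs = simulate_bipartite_knn(12, 12, labels, labels, k=3,
                                         within_type_bias=0.5, seed=9)
        path = tmp_path / "graph.tsv"
        write_graph_tsv(g, path)
        back = read_graph_tsv(path, {nid: nid.split(":")[0] for nid in g.node_ids})
        assert back.node_ids == g.node_ids
        assert np.array_equal(back.neighbors, g.neighbors)
        assert similarity_scores(back, labs).equals(similarity_scores(g, labs))
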