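"""PAD similarity network: averaging, 2-NN retention with ties, exports."""

import itertools

import numpy as np
import pytest

from padmine.padnet import SimilarityMatrix, build_knn_network, pad_similarity


def toy_sim():
    ids = ["m1", "m2", "m3"]
    vals = np.array(
        [
            [1.0, 0.4, 0.2],
            [0.4, 1.0, 0.6],
            [0.2, 0.6, 1.0],
        ]
    )
    return SimilarityMatrix(ids, vals)


class TestSimilarityMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            SimilarityMatrix(["a", "b"], np.array([[0.9, 0.2], [0.2, 1.0]]))

    def test_tsv_roundtrip(self, tmp_path):
        sim = toy_sim()
        path = tmp_path / "sim.tsv"
        sim.write_tsv(path)
        back = SimilarityMatrix.read_tsv(path)
        assert back.ids == sim.ids
        assert np.allclose(back.values, sim.values)


class TestPadSimilarity:
    def test_identical_singletons(self):
        assert pad_similarity({"m1"}, {"m1"}, toy_sim()) == 1.0

    def test_single_pair(self):
        assert pad_similarity({"m1"}, {"m2"}, toy_sim()) == pytest.approx(0.4)

    def test_mean_over_all_pairs(self):
        # supports {m1,m2,m3} x {m2,m3}: mean of the 6 table entries
        sim = toy_sim()
        expected = (0.4 + 0.2 + 1.0 + 0.6 + 0.6 + 1.0) / 6
        assert pad_similarity({"m1", "m2", "m3"}, {"m2", "m3"}, sim) == pytest.approx(expected)

    def test_missing_molecule_named(self):
        with pytest.raises(KeyError, match="mX"):
            pad_similarity({"m1"}, {"mX"}, toy_sim())


def random_instance(n_pads=8, n_mols=15, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"m{i}" for i in range(n_mols)]
    raw = rng.uniform(0.0, 1.0, size=(n_mols, n_mols))
    vals = (raw + raw.T) / 2
    np.fill_diagonal(vals, 1.0)
    sim = SimilarityMatrix(ids, vals)
    pads = {
        f"p{i}": frozenset(rng.choice(ids, size=rng.integers(2, 6), replace=False))
        for i in range(n_pads)
    }
    return pads, sim


class TestKnnNetwork:
    def test_three_pads_complete(self):
        pads, sim = random_instance(n_pads=3, seed=1)
        g = build_knn_network(pads, sim, k=2)
        assert g.number_of_edges() == 3  # complete graph on 3 nodes

    def test_matches_rank_and_keep_oracle(self):
        pads, sim = random_instance(seed=2)
        g = build_knn_network(pads, sim, k=2)
        names = sorted(pads)
        expected = set()
        for a in names:
            sims = sorted(
                ((pad_similarity(pads[a], pads[b], sim), b) for b in names if b != a),
                reverse=True,
            )
            cutoff = sims[1][0]  # k-th best similarity (k = 2)
            for s, b in sims:
                if s >= cutoff:
                    expected.add(frozenset((a, b)))
        assert {frozenset(e) for e in g.edges} == expected

    def test_ties_at_rank_k_all_retained(self):
        # four PADs with one molecule each; p0 equally similar to p2 and p3
        ids = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [1.0, 0.9, 0.5, 0.5],
                [0.9, 1.0, 0.1, 0.1],
                [0.5, 0.1, 1.0, 0.2],
                [0.5, 0.1, 0.2, 1.0],
            ]
        )
        sim = SimilarityMatrix(ids, vals)
        pads = {f"p{i}": frozenset({ids[i]}) for i in range(4)}
        g = build_knn_network(pads, sim, k=2)
        # p0's rank-2 value 0.5 is shared by p2 and p3: both kept
        assert {"p1", "p2", "p3"} <= set(g.neighbors("p0"))

    def test_order_invariance(self):
        pads, sim = random_instance(seed=3)
        g1 = build_knn_network(dict(sorted(pads.items())), sim, k=2)
        g2 = build_knn_network(dict(sorted(pads.items(), reverse=True)), sim, k=2)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_k_monotone_growth(self):
        pads, sim = random_instance(seed=4)
        edges = [
            set(map(frozenset, build_knn_network(pads, sim, k=k).edges))
            for k in (1, 2, 5)
        ]
        assert edges[0] <= edges[1] <= edges[2]

    def test_no_self_edges_and_weights_in_range(self):
        pads, sim = random_instance(seed=5)
        g = build_knn_network(pads, sim, k=2)
        for u, v, data in g.edges(data=True):
            assert u != v
            assert 0.0 <= data["weight"] <= 1.0

    def test_node_attributes_and_export(self, tmp_path):
        import networkx as nx

        pads, sim = random_instance(n_pads=4, seed=6)
        attrs = {v: {"polarity": "active" if i % 2 else "inactive"} for i, v in enumerate(sorted(pads))}
        g = build_knn_network(pads, sim, k=2, attributes=attrs)
        from padmine.padnet import write_pad_graphml, write_pad_sif

        gml = tmp_path / "pad.graphml"
        write_pad_graphml(g, gml)
        back = nx.read_graphml(gml)
        assert set(back.nodes) == set(pads)
        sif = tmp_path / "pad.sif"
        write_pad_sif(g, sif)
        assert len(sif.read_text().strip().splitlines()) >= g.number_of_edges()
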