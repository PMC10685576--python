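"""Growth rate, sibling statistics, pertinence, PAD selection, MMR."""

import itertools
import math

import pytest

from padmine.model import Dataset, MoleculeRecord
from padmine.network import PharmNetwork
from padmine.quality import (
    growth_rate,
    mmrfs_select,
    pertinence,
    select_pads,
    sibling_stats,
)

from oracles import greedy_mmr_reference


def labeled_dataset(n_active: int, n_inactive: int) -> Dataset:
    mols = []
    for i in range(n_active + n_inactive):
        value = 50.0 if i < n_active else 500.0
        mols.append(
            MoleculeRecord(f"m{i}", (("A", 0),), ((0,),), activity_value=value)
        )
    return Dataset(mols)


def ids(lo, hi):
    return frozenset(f"m{i}" for i in range(lo, hi))


class TestGrowthRate:
    def test_equal_frequencies_give_half(self):
        ds = labeled_dataset(10, 10)
        q = growth_rate(ids(5, 15), ds)  # 5 actives, 5 inactives
        assert q.gr == 1.0
        assert q.gr_n == 0.5

    def test_gr_three_gives_075(self):
        ds = labeled_dataset(10, 10)
        q = growth_rate(ids(0, 6) | ids(10, 12), ds)  # 6/10 vs 2/10
        assert q.gr == pytest.approx(3.0)
        assert q.gr_n == pytest.approx(0.75)

    def test_extremes(self):
        ds = labeled_dataset(10, 10)
        only_active = growth_rate(ids(0, 4), ds)
        assert only_active.gr_n == 1.0 and math.isinf(only_active.gr)
        only_inactive = growth_rate(ids(10, 14), ds)
        assert only_inactive.gr_n == 0.0 and only_inactive.gr == 0.0

    def test_gr_n_consistent_with_gr(self):
        ds = labeled_dataset(8, 12)
        for a_hi, i_hi in [(3, 14), (8, 13), (1, 20)]:
            q = growth_rate(ids(0, a_hi) | ids(8, i_hi), ds)
            assert q.gr_n == pytest.approx(q.gr / (q.gr + 1))

    def test_monotone_in_active_hits_and_bounded(self):
        ds = labeled_dataset(10, 10)
        vals = [growth_rate(ids(0, a) | ids(10, 13), ds).gr_n for a in range(1, 11)]
        assert vals == sorted(vals)
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_errors(self):
        ds = labeled_dataset(5, 5)
        with pytest.raises(ValueError):
            growth_rate(frozenset(), ds)
        with pytest.raises(ValueError):
            growth_rate(frozenset({"nope"}), ds)
        unlabeled = Dataset(
            [MoleculeRecord("u", (("A", 0),), ((0,),))], activity_cutoff=100.0
        )
        with pytest.raises(ValueError):
            growth_rate(frozenset({"u"}), unlabeled)


def star_network(qualities: dict[str, float]) -> PharmNetwork:
    """One parent 'root' covering every other vertex: all children are
    mutual siblings."""
    net = PharmNetwork()
    net.add_vertex("root", None, frozenset({"m"}))
    for v in qualities:
        net.add_vertex(v, None, frozenset({"m"}))
        net.add_edge("root", v)
    return net


class TestSiblingStats:
    def test_constant_siblings(self):
        net = star_network({"a": 0.5, "b": 0.5, "c": 0.7})
        q = {"a": 0.5, "b": 0.5, "c": 0.7, "root": 0.5}
        mu, sigma, card = sibling_stats(net, q, "c")
        assert (mu, sigma, card) == (0.5, 0.0, 2)

    def test_population_standard_deviation(self):
        # siblings {0, 1}: mu 0.5, population sigma 0.5 (divide by Card)
        net = star_network({"a": 0.0, "b": 1.0, "c": 0.5})
        q = {"a": 0.0, "b": 1.0, "c": 0.5, "root": 0.5}
        mu, sigma, card = sibling_stats(net, q, "c")
        assert mu == pytest.approx(0.5)
        assert sigma == pytest.approx(0.5)
        assert card == 2

    def test_no_siblings_undefined(self):
        net = star_network({"a": 0.5})
        q = {"a": 0.5, "root": 0.5}
        assert sibling_stats(net, q, "root") == (None, None, 0)
        assert pertinence(net, q, "root") is None


class TestPertinence:
    def test_at_mean_is_zero(self):
        net = star_network({"a": 0.4, "b": 0.6, "c": 0.5})
        q = {"a": 0.4, "b": 0.6, "c": 0.5, "root": 0.0}
        assert pertinence(net, q, "c") == pytest.approx(0.0)

    def test_two_sigma_deviation(self):
        net = star_network({"a": 0.4, "b": 0.6, "c": 0.7})
        q = {"a": 0.4, "b": 0.6, "c": 0.7, "root": 0.0}
        # siblings of c: {a, b}: mu 0.5, sigma 0.1; c deviates by 2 sigma
        assert pertinence(net, q, "c") == pytest.approx(2.0)

    def test_planted_outlier_formula(self):
        net = star_network({"s1": 0.4, "s2": 0.5, "s3": 0.6, "x": 1.0})
        q = {"s1": 0.4, "s2": 0.5, "s3": 0.6, "x": 1.0, "root": 0.0}
        mu, sigma, _ = sibling_stats(net, q, "x")
        assert pertinence(net, q, "x") == pytest.approx((1.0 - mu) / sigma)

    def test_zero_sigma_nonzero_deviation_is_infinite(self):
        net = star_network({"a": 0.5, "b": 0.5, "c": 0.9})
        q = {"a": 0.5, "b": 0.5, "c": 0.9, "root": 0.0}
        assert pertinence(net, q, "c") == math.inf  # siblings {a, b} agree at 0.5

    def test_zero_sigma_zero_deviation_is_zero(self):
        net = star_network({"a": 0.5, "b": 0.5, "d": 0.5})
        q = {"a": 0.5, "b": 0.5, "d": 0.5, "root": 0.0}
        assert pertinence(net, q, "d") == pytest.approx(0.0)


class TestSelectPads:
    def test_uniform_quality_yields_no_pads(self):
        net = star_network({f"v{i}": 0.5 for i in range(5)})
        q = {v: 0.5 for v in list(net.vertices)}
        recs = select_pads(net, q, delta=1.0)
        assert not any(r.is_pad for r in recs)

    def test_planted_outlier_flagged(self):
        qualities = {"s1": 0.4, "s2": 0.5, "s3": 0.6, "s4": 0.5, "x": 1.0}
        net = star_network(qualities)
        q = dict(qualities, root=0.5)
        recs = {r.vertex: r for r in select_pads(net, q, delta=1.64)}
        assert recs["x"].is_pad
        assert not any(recs[s].is_pad for s in ("s1", "s2", "s3", "s4"))
        assert not recs["root"].is_pad  # no siblings: never a PAD

    def test_infinite_pertinence_is_pad(self):
        qualities = {"a": 0.5, "b": 0.5, "c": 0.9}
        net = star_network(qualities)
        q = dict(qualities, root=0.5)
        recs = {r.vertex: r for r in select_pads(net, q, delta=3.0)}
        assert recs["c"].is_pad and recs["c"].pertinence == math.inf

    def test_count_monotone_in_delta(self):
        qualities = {f"v{i}": 0.1 * i for i in range(10)}
        net = star_network(qualities)
        q = dict(qualities, root=0.5)
        counts = [
            sum(r.is_pad for r in select_pads(net, q, delta=d))
            for d in (1.0, 1.3, 1.64, 1.96, 2.2, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_pure_function(self):
        qualities = {f"v{i}": 0.17 * (i % 5) for i in range(8)}
        net = star_network(qualities)
        q = dict(qualities, root=0.5)
        assert select_pads(net, q, 1.5) == select_pads(net, q, 1.5)


class TestMMRFS:
    def make_records(self, perts):
        from padmine.quality import PertinenceRecord

        return [
            PertinenceRecord(v, 0.5, 3, 0.5, 0.1, p, True, 1.64)
            for v, p in perts.items()
        ]

    def test_identical_supports_deprioritized(self):
        records = self.make_records({"a": 5.0, "b": 2.5, "c": 2.0})
        supports = {
            "a": frozenset({"m1", "m2"}),
            "b": frozenset({"m1", "m2"}),  # clone of a
            "c": frozenset({"m3", "m4"}),  # disjoint
        }
        picked = mmrfs_select(records, supports, k=2, lam=1.0)
        assert picked == ["a", "c"]

    def test_k_equal_all_returns_all_ordered(self):
        records = self.make_records({"a": 1.0, "b": 3.0, "c": 2.0})
        supports = {v: frozenset({v}) for v in "abc"}
        assert mmrfs_select(records, supports, k=3, lam=0.5) == ["b", "c", "a"]

    def test_matches_definition_oracle(self):
        import numpy as np

        rng = np.random.default_rng(42)
        mols = [f"m{i}" for i in range(12)]
        perts = {f"p{i}": float(rng.uniform(1.7, 6.0)) for i in range(10)}
        records = self.make_records(perts)
        supports = {
            v: frozenset(rng.choice(mols, size=rng.integers(2, 6), replace=False))
            for v in perts
        }
        got = mmrfs_select(records, supports, k=3, lam=0.5)
        assert got == greedy_mmr_reference(records, supports, k=3, lam=0.5)

    def test_coverage_stop(self):
        records = self.make_records({"a": 5.0, "b": 4.0, "c": 3.0})
        supports = {
            "a": frozenset({"m1", "m2", "m3"}),
            "b": frozenset({"m4", "m5", "m6"}),
            "c": frozenset({"m7"}),
        }
        picked = mmrfs_select(records, supports, coverage=0.5, n_molecules=10, lam=0.5)
        assert picked == ["a", "b"]  # 6/10 covered after two picks
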