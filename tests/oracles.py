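"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration over
permutations, injections or vertex pairs — and shares no code path with
the package internals it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from padmine.model import Dataset, MoleculeRecord, Pharmacophore


def pairs(order):
    return list(itertools.combinations(range(order), 2))


def permuted_form(p: Pharmacophore, perm) -> tuple[tuple[str, ...], tuple[int, ...]]:
    labels = tuple(p.labels[v] for v in perm)
    dists = tuple(p.distance(perm[i], perm[j]) for i, j in pairs(p.order))
    return labels, dists


def brute_canonical(p: Pharmacophore) -> Pharmacophore:
    """Minimum (labels, distances) over all order! vertex permutations."""
    best = min(permuted_form(p, perm) for perm in itertools.permutations(range(p.order)))
    return Pharmacophore(*best)


def brute_is_sub(p: Pharmacophore, q: Pharmacophore) -> bool:
    """Exhaustive search over all injective vertex maps p -> q."""
    if p.order > q.order:
        return False
    for image in itertools.permutations(range(q.order), p.order):
        if all(q.labels[image[i]] == p.labels[i] for i in range(p.order)) and all(
            q.distance(image[i], image[j]) == p.distance(i, j)
            for i, j in pairs(p.order)
        ):
            return True
    return False


def random_pharmacophore(rng: np.random.Generator, order: int, max_dist: int = 6) -> Pharmacophore:
    from padmine.model import FEATURE_CODES

    labels = tuple(FEATURE_CODES[i] for i in rng.integers(0, 6, order))
    n_pairs = order * (order - 1) // 2
    dists = tuple(int(d) for d in rng.integers(1, max_dist + 1, n_pairs))
    return Pharmacophore(labels, dists)


def brute_mine(dataset: Dataset, min_support: int, max_order: int):
    """Per-molecule exhaustive subset enumeration, canonicalized with the
    brute-force canonical form; returns {notation: frozenset of ids}."""
    supports: dict[str, set[str]] = {}
    for mol in dataset:
        seen: set[str] = set()
        for k in range(1, min(max_order, mol.n_features) + 1):
            for subset in itertools.combinations(range(mol.n_features), k):
                ok = True
                dists = []
                for a, b in itertools.combinations(subset, 2):
                    d = mol.dist[a][b]
                    if d is None:
                        ok = False
                        break
                    dists.append(d)
                if not ok:
                    continue
                p = Pharmacophore(tuple(mol.features[i][0] for i in subset), tuple(dists))
                seen.add(brute_canonical(p).notation)
        for key in seen:
            supports.setdefault(key, set()).add(mol.id)
    return {
        key: frozenset(ids) for key, ids in supports.items() if len(ids) >= min_support
    }


def hasse_reduction(notations, pharms) -> set[tuple[str, str]]:
    """Transitive reduction (networkx) of the full strict-containment
    relation computed with the exhaustive injection oracle."""
    g = nx.DiGraph()
    g.add_nodes_from(notations)
    for a, b in itertools.permutations(notations, 2):
        pa, pb = pharms[a], pharms[b]
        if pa.order < pb.order and brute_is_sub(pa, pb):
            g.add_edge(a, b)
    return set(nx.transitive_reduction(g).edges)


def quadratic_siblings(net, v: str) -> set[str]:
    """Scan all vertex pairs for a shared parent."""
    pv = net.parents(v)
    return {
        w for w in net.vertices if w != v and pv & net.parents(w)
    }


def greedy_mmr_reference(records, supports, k: int, lam: float) -> list[str]:
    """Step-wise argmax straight from the marginal-relevance definition,
    written independently of the implementation."""

    def jac(a, b):
        u = a | b
        return len(a & b) / len(u) if u else 0.0

    pool = {r.vertex: abs(r.pertinence) for r in records}
    picked: list[str] = []
    while pool and len(picked) < k:
        scored = []
        for v, rel in pool.items():
            red = max((jac(supports[v], supports[c]) for c in picked), default=0.0)
            scored.append((-(rel - lam * red), v))
        scored.sort()
        best = scored[0][1]
        picked.append(best)
        del pool[best]
    return picked
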