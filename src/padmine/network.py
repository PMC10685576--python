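"""Pharmacophore network: the Hasse diagram of the subgraph partial order.

Vertices are mined pharmacophores (or, after condensation, equivalence
classes); a directed edge (v1, v2) exists iff v1 ⊂ v2 and no third vertex
v3 of the network satisfies v1 ⊂ v3 ⊂ v2 — the cover relation.  The edge
relation is written v1 < v2; v1 is a parent of v2 and v2 a child of v1.
A *sibling* of v is any other vertex sharing at least one parent with v.

Cover edges may span more than one order when intermediate patterns fall
below the support threshold: the cover condition quantifies only over
vertices actually present.
"""

from __future__ import annotations

from typing import Any, Hashable, Iterable, Mapping

import networkx as nx

from .mining import SupportIndex
from .model import Pharmacophore, is_subpharmacophore

__all__ = ["PharmNetwork", "build_network", "cover_edges"]


class PharmNetwork:
    """Hasse diagram with supports and payloads attached to the vertices.

    Thin wrapper over a :class:`networkx.DiGraph`; vertex ids are
    canonical notation strings (or representative notations for
    equivalence-class networks), stable across runs.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # construction ---------------------------------------------------------
    def add_vertex(self, vid: str, payload: Any, support: frozenset[str], **attrs) -> None:
        self.graph.add_node(vid, payload=payload, support=frozenset(support), **attrs)

    def add_edge(self, parent: str, child: str) -> None:
        if parent not in self.graph or child not in self.graph:
            raise KeyError(f"unknown vertex in edge ({parent!r}, {child!r})")
        self.graph.add_edge(parent, child)

    # queries --------------------------------------------------------------
    def _check(self, v: str) -> None:
        if v not in self.graph:
            raise KeyError(f"unknown vertex {v!r}")

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, v: str) -> bool:
        return v in self.graph

    def payload(self, v: str) -> Any:
        self._check(v)
        return self.graph.nodes[v]["payload"]

    def support(self, v: str) -> frozenset[str]:
        self._check(v)
        return self.graph.nodes[v]["support"]

    def parents(self, v: str) -> set[str]:
        """Hasse-edge predecessors of ``v`` (covers, not all ancestors)."""
        self._check(v)
        return set(self.graph.predecessors(v))

    def children(self, v: str) -> set[str]:
        self._check(v)
        return set(self.graph.successors(v))

    def siblings(self, v: str) -> set[str]:
        """Vertices other than ``v`` sharing at least one parent with it."""
        self._check(v)
        out: set[str] = set()
        for p in self.graph.predecessors(v):
            out.update(self.graph.successors(p))
        out.discard(v)
        return out

    def card(self, v: str) -> int:
        """Number of siblings of ``v``."""
        return len(self.siblings(v))

    # export ---------------------------------------------------------------
    def write_graphml(self, path, extra: Mapping[str, Mapping[str, Any]] | None = None) -> None:
        """GraphML export with flat vertex attributes, Cytoscape-friendly.

        ``extra`` maps vertex id -> {attribute: value} for e.g. GR_N.
        """
        g = nx.DiGraph()
        for v in self.graph.nodes:
            payload = self.graph.nodes[v]["payload"]
            attrs: dict[str, Any] = {
                "notation": v,
                "support_size": len(self.graph.nodes[v]["support"]),
            }
            order = getattr(payload, "order", None)
            if order is not None:
                attrs["order"] = int(order)
            if extra and v in extra:
                for k, val in extra[v].items():
                    if val is not None:
                        attrs[k] = val
            g.add_node(v, **attrs)
        g.add_edges_from(self.graph.edges)
        nx.write_graphml(g, path)

    def write_sif(self, path, relation: str = "covers") -> None:
        """Simple-interaction-format export (one ``parent covers child``
        line per edge; isolated vertices on their own line)."""
        with open(path, "w") as fh:
            isolated = [v for v in sorted(self.graph.nodes) if self.graph.degree(v) == 0]
            for u, v in sorted(self.graph.edges):
                fh.write(f"{u}\t{relation}\t{v}\n")
            for v in isolated:
                fh.write(f"{v}\n")


def cover_edges(
    nodes: Iterable[Hashable], lt: set[tuple[Hashable, Hashable]]
) -> set[tuple[Hashable, Hashable]]:
    """Cover pairs (Hasse edges) of a strict partial order given as a set
    of (smaller, larger) pairs: keep (u, v) iff no w has (u, w) and (w, v).
    """
    preds: dict[Hashable, list[Hashable]] = {v: [] for v in nodes}
    for u, v in lt:
        preds[v].append(u)
    ltset = lt
    out: set[tuple[Hashable, Hashable]] = set()
    for v, ps in preds.items():
        for u in ps:
            if not any(w != u and (u, w) in ltset for w in ps):
                out.add((u, v))
    return out


def build_network(index: SupportIndex) -> PharmNetwork:
    """Build the Hasse diagram of the ⊂ order over the mined patterns.

    Containment testing is pruned by order and by support inclusion
    (p ⊂ q forces Support(q) ⊆ Support(p)) and by label-multiset
    inclusion before running the exact subgraph test.
    """
    if len(index) == 0:
        raise ValueError("cannot build a network from an empty index")
    net = PharmNetwork()
    items: list[tuple[str, Pharmacophore, frozenset[str]]] = []
    for key in index.notations():
        p, supp = index.entries[key]
        net.add_vertex(key, p, supp)
        items.append((key, p, supp))

    from collections import Counter

    label_counts = {key: Counter(p.labels) for key, p, _ in items}
    by_order: dict[int, list[tuple[str, Pharmacophore, frozenset[str]]]] = {}
    for it in items:
        by_order.setdefault(it[1].order, []).append(it)

    lt: set[tuple[str, str]] = set()
    orders = sorted(by_order)
    for ka in orders:
        for kb in orders:
            if kb <= ka:
                continue
            for key_p, p, supp_p in by_order[ka]:
                cp = label_counts[key_p]
                for key_q, q, supp_q in by_order[kb]:
                    if not supp_q <= supp_p:
                        continue
                    cq = label_counts[key_q]
                    if any(cq[l] < n for l, n in cp.items()):
                        continue
                    if is_subpharmacophore(p, q):
                        lt.add((key_p, key_q))

    for u, v in cover_edges([it[0] for it in items], lt):
        net.add_edge(u, v)
    return net
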