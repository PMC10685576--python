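"""Equivalence classes of pharmacophores sharing a support set.

Mined pattern sets are highly redundant: many patterns occur in exactly
the same molecules.  Three nested groupings condense them:

* **GEC** (general): all vertices with the same support set.
* **DEC** (divided): a GEC refined by pattern order.
* **SEC** (structured): a GEC refined by connectivity — members must be
  linked by a path that stays inside the class, treating Hasse edges as
  undirected (the underlying adjacency relation is symmetric).

Inside a class, *generators* are members with no parent in the class and
*closed* members have no child in the class; the class representative is
the generator with the lexicographically smallest notation.  The
condensed EC network lifts the pharmacophore-level edge relation
(EC1 < EC2 iff some member edge crosses from EC1 to EC2) and re-reduces
it to cover edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import PharmNetwork, cover_edges

__all__ = [
    "EquivalenceClass",
    "compute_gec",
    "compute_dec",
    "compute_sec",
    "find_generators",
    "find_closed",
    "build_ec_network",
]


@dataclass(frozen=True)
class EquivalenceClass:
    """A set of network vertices sharing one support set."""

    kind: str  # "GEC" | "DEC" | "SEC"
    members: frozenset[str]
    support: frozenset[str]
    generators: frozenset[str]
    closed: frozenset[str]
    representative: str
    order: int | None = None  # shared member order (DEC only)

    def __post_init__(self) -> None:
        if self.kind not in ("GEC", "DEC", "SEC"):
            raise ValueError(f"unknown EC kind {self.kind!r}")
        if not self.members:
            raise ValueError("an equivalence class cannot be empty")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def representative_order(self) -> int:
        """Order of the representative generator; the order an EC is
        booked under in distribution histograms."""
        # representative notation "|A|D| |3|": order = labels in first block
        head = self.representative.split()[0]
        return len(head.strip("|").split("|"))


def _in_class_generators(members: frozenset[str], net: PharmNetwork) -> frozenset[str]:
    return frozenset(m for m in members if not (net.parents(m) & members))


def _in_class_closed(members: frozenset[str], net: PharmNetwork) -> frozenset[str]:
    return frozenset(m for m in members if not (net.children(m) & members))


def _make_ec(
    kind: str, members: frozenset[str], net: PharmNetwork, order: int | None = None
) -> EquivalenceClass:
    gens = _in_class_generators(members, net)
    closed = _in_class_closed(members, net)
    support = net.support(next(iter(members)))
    return EquivalenceClass(
        kind=kind,
        members=members,
        support=support,
        generators=gens,
        closed=closed,
        representative=min(gens),
        order=order,
    )


def find_generators(ec: EquivalenceClass, net: PharmNetwork) -> frozenset[str]:
    """Members with no Hasse parent inside the class."""
    return _in_class_generators(ec.members, net)


def find_closed(ec: EquivalenceClass, net: PharmNetwork) -> frozenset[str]:
    """Members with no Hasse child inside the class."""
    return _in_class_closed(ec.members, net)


def compute_gec(net: PharmNetwork) -> list[EquivalenceClass]:
    """Partition the vertices by support set (general equivalence classes);
    connectivity is irrelevant."""
    groups: dict[frozenset[str], set[str]] = {}
    for v in net.vertices:
        groups.setdefault(net.support(v), set()).add(v)
    return sorted(
        (_make_ec("GEC", frozenset(ms), net) for ms in groups.values()),
        key=lambda ec: ec.representative,
    )


def compute_dec(net: PharmNetwork) -> list[EquivalenceClass]:
    """Refine GECs by pattern order (divided equivalence classes)."""
    groups: dict[tuple[frozenset[str], int], set[str]] = {}
    for v in net.vertices:
        order = net.payload(v).order
        groups.setdefault((net.support(v), order), set()).add(v)
    return sorted(
        (
            _make_ec("DEC", frozenset(ms), net, order=key[1])
            for key, ms in groups.items()
        ),
        key=lambda ec: ec.representative,
    )


def compute_sec(net: PharmNetwork) -> list[EquivalenceClass]:
    """Refine GECs by in-class connectivity (structured equivalence
    classes): connected components of the subgraph induced by each GEC,
    ignoring edge direction."""
    out: list[EquivalenceClass] = []
    groups: dict[frozenset[str], set[str]] = {}
    for v in net.vertices:
        groups.setdefault(net.support(v), set()).add(v)
    undirected = net.graph.to_undirected(as_view=True)
    for members in groups.values():
        sub = undirected.subgraph(members)
        for comp in nx.connected_components(sub):
            out.append(_make_ec("SEC", frozenset(comp), net))
    return sorted(out, key=lambda ec: ec.representative)


def build_ec_network(ecs: list[EquivalenceClass], net: PharmNetwork) -> PharmNetwork:
    """Condense the network to one vertex per equivalence class.

    EC1 < EC2 holds iff some Hasse edge of the underlying network crosses
    from a member of EC1 to a member of EC2; the lifted relation is then
    reduced to its cover edges.  The classes must partition the vertex
    set.
    """
    member_of: dict[str, int] = {}
    for i, ec in enumerate(ecs):
        for m in ec.members:
            if m in member_of:
                raise ValueError(f"vertex {m!r} belongs to more than one class")
            member_of[m] = i
    missing = set(net.vertices) - set(member_of)
    if missing:
        raise ValueError(f"classes do not cover vertices: {sorted(missing)[:5]}")

    raw: set[tuple[int, int]] = set()
    for u, v in net.edges:
        a, b = member_of[u], member_of[v]
        if a != b:
            raw.add((a, b))
    # lifted relation is transitive-closed before reduction: EC order is
    # the transitive closure of the crossing-edge relation
    g = nx.DiGraph()
    g.add_nodes_from(range(len(ecs)))
    g.add_edges_from(raw)
    closure: set[tuple[int, int]] = set()
    for a in g.nodes:
        for b in nx.descendants(g, a):
            closure.add((a, b))

    out = PharmNetwork()
    for ec in ecs:
        out.add_vertex(ec.representative, ec, ec.support)
    for a, b in cover_edges(range(len(ecs)), closure):
        out.add_edge(ecs[a].representative, ecs[b].representative)
    return out
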