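"""Core data model: topological pharmacophores, molecules and the subgraph order.

A topological (2D) pharmacophore is a complete vertex- and edge-labeled
graph: vertices carry one of six pharmacophoric feature kinds and every
pair of vertices carries the length (in bonds) of the shortest bond path
between the two feature anchors in a supporting molecule.  The number of
features is the *order* of the pharmacophore.

Feature kinds
-------------
==== =========================
A    hydrogen-bond acceptor
D    hydrogen-bond donor
N    negatively ionizable group
P    positively ionizable group
H    hydrophobic region
R    aromatic ring
==== =========================

Pharmacophores are written in a fixed pipe-delimited notation: the
feature labels first, then the pairwise distances in row-major
upper-triangle order, e.g. ``|A|A| |2|`` for two acceptors two bonds
apart, or ``|A|A|H|D| |2|4|5|7|1|3|`` where the six distances pair
feature 1 against 2, 3, 4, then 2 against 3, 4, then 3 against 4.
Canonical pharmacophores (lexicographically minimal over vertex
permutations) make the notation string usable as an identity key.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "FEATURE_CODES",
    "Pharmacophore",
    "MoleculeRecord",
    "Dataset",
    "NotationError",
    "parse_notation",
    "to_notation",
    "canonicalize",
    "is_subpharmacophore",
    "embedded_pharmacophores",
    "embeds",
]

#: The six pharmacophoric feature codes, in canonical (alphabetical) order.
FEATURE_CODES: tuple[str, ...] = ("A", "D", "H", "N", "P", "R")

_CODE_SET = frozenset(FEATURE_CODES)


class NotationError(ValueError):
    """Raised when a pharmacophore notation string is malformed."""


def _pair_index(i: int, j: int, order: int) -> int:
    """Index of pair (i, j), i < j, in the row-major upper triangle."""
    return i * order - i * (i + 1) // 2 + (j - i - 1)


def _pairs(order: int) -> Iterator[tuple[int, int]]:
    """Vertex pairs in row-major upper-triangle order."""
    return itertools.combinations(range(order), 2)


@dataclass(frozen=True)
class Pharmacophore:
    """A complete feature graph: vertex labels plus upper-triangle distances.

    Parameters
    ----------
    labels
        Feature codes, one per vertex, in vertex order.
    distances
        Bond-path distances for vertex pairs (0,1), (0,2), ..., (1,2), ...
        in row-major upper-triangle order; ``order*(order-1)//2`` entries.
    """

    labels: tuple[str, ...]
    distances: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "distances", tuple(int(d) for d in self.distances))
        k = len(self.labels)
        if k < 1:
            raise ValueError("a pharmacophore has at least one feature")
        bad = [l for l in self.labels if l not in _CODE_SET]
        if bad:
            raise ValueError(f"unknown feature code(s): {bad!r}")
        if len(self.distances) != k * (k - 1) // 2:
            raise ValueError(
                f"order {k} needs {k * (k - 1) // 2} distances, "
                f"got {len(self.distances)}"
            )
        if any(d < 0 for d in self.distances):
            raise ValueError("distances are non-negative bond counts")

    @property
    def order(self) -> int:
        """Number of pharmacophoric features."""
        return len(self.labels)

    def distance(self, i: int, j: int) -> int:
        """Distance between vertices ``i`` and ``j`` (0 when ``i == j``)."""
        if i == j:
            return 0
        if i > j:
            i, j = j, i
        return self.distances[_pair_index(i, j, self.order)]

    @property
    def notation(self) -> str:
        return to_notation(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return to_notation(self)


def to_notation(p: Pharmacophore) -> str:
    """Render a pharmacophore in the fixed pipe-delimited notation.

    The inverse of :func:`parse_notation`; for a canonical pharmacophore
    the result is a unique identity string.
    """
    head = "|" + "|".join(p.labels) + "|"
    if p.order == 1:
        return head
    tail = "|" + "|".join(str(d) for d in p.distances) + "|"
    return head + " " + tail


def parse_notation(text: str) -> Pharmacophore:
    """Parse pipe-delimited notation such as ``"|A|A| |2|"``.

    The pharmacophore is returned exactly as written (not canonicalized);
    round-trips through :func:`to_notation`.
    """
    blocks = text.split()
    if not 1 <= len(blocks) <= 2:
        raise NotationError(f"expected one or two pipe blocks, got {text!r}")

    def split_block(block: str, what: str) -> list[str]:
        if len(block) < 3 or not (block.startswith("|") and block.endswith("|")):
            raise NotationError(f"malformed {what} block {block!r}")
        return block[1:-1].split("|")

    labels = split_block(blocks[0], "label")
    for tok in labels:
        if tok not in _CODE_SET:
            raise NotationError(f"unknown feature code {tok!r} in {text!r}")
    k = len(labels)
    n_pairs = k * (k - 1) // 2
    if k == 1:
        if len(blocks) == 2:
            raise NotationError("order-1 pharmacophore takes no distance block")
        return Pharmacophore(tuple(labels))
    if len(blocks) != 2:
        raise NotationError(f"missing distance block in {text!r}")
    raw = split_block(blocks[1], "distance")
    if len(raw) != n_pairs:
        raise NotationError(
            f"order {k} needs {n_pairs} distances, got {len(raw)} in {text!r}"
        )
    dists = []
    for tok in raw:
        if not tok.isdigit():
            raise NotationError(f"bad distance token {tok!r} in {text!r}")
        dists.append(int(tok))
    return Pharmacophore(tuple(labels), tuple(dists))


def _permuted(p: Pharmacophore, perm: Sequence[int]) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Labels and distances of p with new vertex i being old vertex perm[i]."""
    labels = tuple(p.labels[v] for v in perm)
    dists = tuple(p.distance(perm[i], perm[j]) for i, j in _pairs(p.order))
    return labels, dists


def canonicalize(p: Pharmacophore) -> Pharmacophore:
    """Return the lexicographically minimal vertex relabeling of ``p``.

    Minimizes the ``(labels, distances)`` pair with feature codes ordered
    alphabetically (A < D < H < N < P < R).  Idempotent; two
    pharmacophores are equal as graphs iff their canonical forms (hence
    canonical notation strings) are equal.

    Only permutations that keep the label sequence sorted can be minimal,
    so the search runs over the product of permutations within equal-label
    blocks rather than all ``order!`` arrangements.
    """
    k = p.order
    if k == 1:
        return p
    base = sorted(range(k), key=lambda v: p.labels[v])
    labels = tuple(p.labels[v] for v in base)
    # contiguous blocks of equal labels in the sorted arrangement
    blocks: list[list[int]] = []
    for v in base:
        if blocks and p.labels[blocks[-1][0]] == p.labels[v]:
            blocks[-1].append(v)
        else:
            blocks.append([v])
    best: tuple[int, ...] | None = None
    for combo in itertools.product(*(itertools.permutations(b) for b in blocks)):
        perm = tuple(itertools.chain.from_iterable(combo))
        dists = tuple(p.distance(perm[i], perm[j]) for i, j in _pairs(k))
        if best is None or dists < best:
            best = dists
    assert best is not None
    return Pharmacophore(labels, best)


def is_subpharmacophore(p: Pharmacophore, q: Pharmacophore) -> bool:
    """True iff ``p`` embeds into ``q`` (noted p ⊆ q).

    An embedding is an injective vertex map preserving feature labels and
    exact pairwise distances.  The relation is reflexive and, on canonical
    forms, a partial order.
    """
    np_, nq = p.order, q.order
    if np_ > nq:
        return False
    # candidate images per p-vertex, by label
    cand = [[j for j in range(nq) if q.labels[j] == p.labels[i]] for i in range(np_)]
    if any(not c for c in cand):
        return False
    assignment: list[int] = []
    used = [False] * nq

    def extend(i: int) -> bool:
        if i == np_:
            return True
        for j in cand[i]:
            if used[j]:
                continue
            ok = all(
                p.distance(i, a) == q.distance(j, assignment[a])
                for a in range(i)
            )
            if ok:
                used[j] = True
                assignment.append(j)
                if extend(i + 1):
                    return True
                assignment.pop()
                used[j] = False
        return False

    return extend(0)


# ---------------------------------------------------------------------------
# molecules and datasets


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule as an annotated feature graph.

    ``features`` is a sequence of (feature code, anchor id) pairs; the
    anchor is the atom (or synthetic point) index used for distance
    measurement.  ``dist`` is the symmetric table of shortest-bond-path
    distances between feature anchors, with ``None`` marking pairs on
    different fragments (no bond path).
    """

    id: str
    features: tuple[tuple[str, int], ...]
    dist: tuple[tuple[int | None, ...], ...]
    activity_value: float | None = None
    is_active: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple((str(k), int(a)) for k, a in self.features))
        object.__setattr__(
            self, "dist", tuple(tuple(row) for row in self.dist)
        )
        n = len(self.features)
        for code, _ in self.features:
            if code not in _CODE_SET:
                raise ValueError(f"molecule {self.id}: unknown feature code {code!r}")
        if len(set(self.features)) != n:
            raise ValueError(f"molecule {self.id}: duplicate (kind, anchor) feature")
        if len(self.dist) != n or any(len(row) != n for row in self.dist):
            raise ValueError(f"molecule {self.id}: dist table must be {n}x{n}")
        for i in range(n):
            if self.dist[i][i] != 0:
                raise ValueError(f"molecule {self.id}: dist[{i}][{i}] != 0")
            for j in range(i + 1, n):
                if self.dist[i][j] != self.dist[j][i]:
                    raise ValueError(f"molecule {self.id}: dist not symmetric at ({i},{j})")

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class Dataset:
    """An activity-labeled molecule collection.

    A molecule is *active* when its activity value (nM) is less than or
    equal to ``activity_cutoff`` (default 100 nM).  Molecules without an
    activity value are retained (they still support pharmacophores) but
    are excluded from growth-rate counts.
    """

    molecules: list[MoleculeRecord]
    activity_cutoff: float = 100.0

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids are not unique")
        resolved = []
        for m in self.molecules:
            if m.activity_value is not None:
                flag = m.activity_value <= self.activity_cutoff
                if m.is_active is None or m.is_active != flag:
                    m = MoleculeRecord(
                        m.id, m.features, m.dist, m.activity_value, flag
                    )
            resolved.append(m)
        self.molecules = resolved
        self._by_id = {m.id: m for m in self.molecules}

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.molecules)

    def __getitem__(self, mol_id: str) -> MoleculeRecord:
        return self._by_id[mol_id]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    @property
    def active_ids(self) -> frozenset[str]:
        return frozenset(m.id for m in self.molecules if m.is_active is True)

    @property
    def inactive_ids(self) -> frozenset[str]:
        return frozenset(m.id for m in self.molecules if m.is_active is False)

    @property
    def n_active(self) -> int:
        return len(self.active_ids)

    @property
    def n_inactive(self) -> int:
        return len(self.inactive_ids)

    def subset(self, keep: Iterable[str]) -> "Dataset":
        """New dataset restricted to ``keep``, preserving molecule order."""
        keep = set(keep)
        return Dataset(
            [m for m in self.molecules if m.id in keep], self.activity_cutoff
        )


def _induced(m: MoleculeRecord, subset: Sequence[int]) -> Pharmacophore | None:
    """Induced pharmacophore of the feature-point subset, or None if a
    pair is unreachable (different fragments)."""
    labels = tuple(m.features[i][0] for i in subset)
    dists = []
    for a, b in _pairs(len(subset)):
        d = m.dist[subset[a]][subset[b]]
        if d is None:
            return None
        dists.append(d)
    return Pharmacophore(labels, tuple(dists))


def embedded_pharmacophores(m: MoleculeRecord, k: int) -> set[Pharmacophore]:
    """All canonical order-``k`` pharmacophores embedded in molecule ``m``.

    Every ``k``-subset of the molecule's feature points whose pairwise
    distances are all defined (same fragment) induces one pattern;
    duplicates collapse to their canonical form.
    """
    if k < 1:
        raise ValueError("order must be >= 1")
    out: set[Pharmacophore] = set()
    for subset in itertools.combinations(range(m.n_features), k):
        p = _induced(m, subset)
        if p is not None:
            out.add(canonicalize(p))
    return out


def embeds(m: MoleculeRecord, p: Pharmacophore) -> bool:
    """True iff molecule ``m`` contains pharmacophore ``p``: some injective
    assignment of features to feature points matches all labels and exact
    distances."""
    k = p.order
    n = m.n_features
    if k > n:
        return False
    cand = [
        [j for j in range(n) if m.features[j][0] == p.labels[i]] for i in range(k)
    ]
    if any(not c for c in cand):
        return False
    chosen: list[int] = []
    used = [False] * n

    def extend(i: int) -> bool:
        if i == k:
            return True
        for j in cand[i]:
            if used[j]:
                continue
            ok = all(
                m.dist[j][chosen[a]] is not None
                and m.dist[j][chosen[a]] == p.distance(i, a)
                for a in range(i)
            )
            if ok:
                used[j] = True
                chosen.append(j)
                if extend(i + 1):
                    return True
                chosen.pop()
                used[j] = False
        return False

    return extend(0)
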