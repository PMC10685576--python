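"""Frequent-pharmacophore extraction with minimum support.

Enumeration is level-wise (Apriori-style): order-1 patterns come straight
from the feature points; an order-(k+1) candidate is generated only by
extending a witness embedding of a frequent order-k pattern by one more
feature point with all pairwise distances defined.  Support is
anti-monotone under the subgraph order (p ⊂ q implies
Support(q) ⊆ Support(p)), which makes the level-wise pruning sound and
complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import (
    Dataset,
    Pharmacophore,
    _induced,
    canonicalize,
    embeds,
)

__all__ = ["SupportIndex", "mine", "support_of"]

SOFT_MAX_ORDER = 7


@dataclass
class SupportIndex:
    """Mined pharmacophores keyed by canonical notation, with supports.

    ``entries`` maps canonical notation string -> (pharmacophore,
    frozenset of supporting molecule ids).  Every entry's support has at
    least ``min_support`` members.
    """

    entries: dict[str, tuple[Pharmacophore, frozenset[str]]]
    min_support: int
    max_order: int
    dataset: Dataset | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, notation: str) -> bool:
        return notation in self.entries

    def __iter__(self):
        return iter(self.entries)

    def pharmacophore(self, notation: str) -> Pharmacophore:
        return self.entries[notation][0]

    def support(self, notation: str) -> frozenset[str]:
        return self.entries[notation][1]

    def notations(self) -> list[str]:
        """Canonical notations, sorted for deterministic iteration."""
        return sorted(self.entries)


def mine(dataset: Dataset, min_support: int = 10, max_order: int = 7) -> SupportIndex:
    """Enumerate all pharmacophores of order 1..max_order supported by at
    least ``min_support`` molecules, with exact support sets.

    Parameters mirror the usual extraction settings for activity-labeled
    sets: minimum support 10 molecules and orders 1 to 7 by default.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if len(dataset) == 0:
        raise ValueError("cannot mine an empty dataset")
    if max_order > SOFT_MAX_ORDER:
        warnings.warn(
            f"max_order {max_order} exceeds the usual cap of {SOFT_MAX_ORDER}; "
            "enumeration may be very slow",
            stacklevel=2,
        )
    for m in dataset:
        if m.n_features == 0:
            warnings.warn(f"molecule {m.id} has no features; it supports nothing", stacklevel=2)

    entries: dict[str, tuple[Pharmacophore, frozenset[str]]] = {}

    # level 1: one witness per feature point
    # witnesses: notation -> {molecule id -> set of feature-index frozensets}
    witnesses: dict[str, dict[str, set[frozenset[int]]]] = {}
    patterns: dict[str, Pharmacophore] = {}
    for m in dataset:
        for i, (code, _anchor) in enumerate(m.features):
            p = Pharmacophore((code,))
            key = p.notation
            patterns.setdefault(key, p)
            witnesses.setdefault(key, {}).setdefault(m.id, set()).add(frozenset((i,)))

    level = 1
    while witnesses and level <= max_order:
        frequent = {
            key: wit for key, wit in witnesses.items() if len(wit) >= min_support
        }
        for key, wit in frequent.items():
            entries[key] = (patterns[key], frozenset(wit))
        if level == max_order:
            break
        next_wit: dict[str, dict[str, set[frozenset[int]]]] = {}
        next_pat: dict[str, Pharmacophore] = {}
        for key, wit in frequent.items():
            for mol_id, subsets in wit.items():
                mol = dataset[mol_id]
                seen_here: set[frozenset[int]] = set()
                for subset in subsets:
                    for f in range(mol.n_features):
                        if f in subset:
                            continue
                        if any(mol.dist[f][s] is None for s in subset):
                            continue
                        new = subset | {f}
                        if new in seen_here:
                            continue
                        seen_here.add(new)
                        induced = _induced(mol, sorted(new))
                        assert induced is not None
                        canon = canonicalize(induced)
                        ckey = canon.notation
                        next_pat.setdefault(ckey, canon)
                        next_wit.setdefault(ckey, {}).setdefault(mol_id, set()).add(new)
        witnesses = next_wit
        patterns = next_pat
        level += 1

    return SupportIndex(entries, min_support, max_order, dataset)


def support_of(index: SupportIndex, p: Pharmacophore) -> frozenset[str]:
    """Support of ``p``: the indexed set when present, otherwise computed
    on the fly by embedding ``p`` into every molecule of the indexed
    dataset."""
    canon = canonicalize(p)
    key = canon.notation
    if key in index.entries:
        return index.entries[key][1]
    if index.dataset is None:
        raise KeyError(
            f"{key} is not indexed and the index carries no dataset to scan"
        )
    return frozenset(m.id for m in index.dataset if embeds(m, canon))
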