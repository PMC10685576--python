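"""Stratified k-fold stability of PAD selection.

Discovered PADs risk being artifacts of the particular molecule sample:
a PAD's identification depends not only on its own support and quality
but on which siblings made it into the network at all.  The protocol
splits the data into k stratified folds (equal active/inactive
proportions), re-runs the whole pipeline on each of the k
leave-one-fold-out subsets (each holding (k-1)/k of the data), and counts
in how many subsets each PAD reappears.

Two subsets share a fraction (k-2)/(k-1) of the molecules (0.88889 for
k = 10), so by data overlap alone a pattern would be expected to reoccur
in m subsets with probability at most ((k-2)/(k-1))^m — the heuristic
chance baseline reported alongside the observed reoccurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Dataset
from .quality import PertinenceRecord

__all__ = ["StabilityReport", "stratified_folds", "chance_reoccurrence", "run_stability"]


@dataclass
class StabilityReport:
    """Aggregated per-fold pipeline outcomes and PAD reoccurrence."""

    n_folds: int
    #: one (n_pharmacophores, n_secs, n_pads_pos, n_pads_neg) per subset
    per_fold: list[tuple[int, int, int, int]]
    #: PAD id -> number of subsets it was selected in (all PADs)
    reoccurrence: dict[str, int]
    #: same, split by pertinence sign
    reoccurrence_pos: dict[str, int]
    reoccurrence_neg: dict[str, int]
    #: m -> number of PADs present in >= m subsets
    cumulative: dict[int, int]
    cumulative_pos: dict[int, int]
    cumulative_neg: dict[int, int]
    #: m -> chance-overlap baseline ((k-2)/(k-1))^m
    chance_curve: dict[int, float]


def stratified_folds(dataset: Dataset, k: int, seed: int) -> list[Dataset]:
    """The k leave-one-fold-out subsets of a stratified k-fold split.

    Each class (active / inactive / unlabeled) is shuffled independently
    with the seed and dealt round-robin into k folds, so every fold keeps
    the class proportions within rounding; subset i is the whole dataset
    minus fold i.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    strata: list[list[str]] = [
        sorted(dataset.active_ids),
        sorted(dataset.inactive_ids),
        sorted(
            m.id for m in dataset if m.is_active is None
        ),
    ]
    for label, ids in zip(("active", "inactive"), strata):
        if ids and len(ids) < k:
            raise ValueError(f"{label} class has {len(ids)} < k={k} members")
    fold_of: dict[str, int] = {}
    for ids in strata:
        ids = list(ids)
        rng.shuffle(ids)
        for pos, mol_id in enumerate(ids):
            fold_of[mol_id] = pos % k
    subsets = []
    for i in range(k):
        keep = [m.id for m in dataset if fold_of[m.id] != i]
        subsets.append(dataset.subset(keep))
    return subsets


def chance_reoccurrence(k_folds: int, m: int) -> float:
    """Chance baseline for a pattern reoccurring in m of the k subsets:
    ((k-2)/(k-1))^m — the pairwise subset overlap raised to m."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if m < 0:
        raise ValueError("m must be >= 0")
    return ((k_folds - 2) / (k_folds - 1)) ** m


def _pad_ids(records: list[PertinenceRecord]) -> tuple[set[str], set[str]]:
    """PAD ids split by pertinence sign.  At SEC level the vertex id is
    already the representative generator notation."""
    pos, neg = set(), set()
    for r in records:
        if not r.is_pad:
            continue
        (pos if (r.pertinence is not None and r.pertinence > 0) else neg).add(r.vertex)
    return pos, neg


def run_stability(dataset: Dataset, params: dict, k: int = 10, seed: int = 0) -> StabilityReport:
    """Run the full pipeline independently on each leave-one-fold-out
    subset and score PAD reoccurrence.

    ``params`` holds the pipeline settings (``min_support``,
    ``max_order``, ``delta``, ``network_level``).  PAD identity across
    subsets is the vertex id: canonical notation at pharmacophore level,
    representative generator notation at SEC level.
    """
    from .pipeline import analyze  # local import to avoid a cycle

    per_fold: list[tuple[int, int, int, int]] = []
    seen_pos: dict[str, int] = {}
    seen_neg: dict[str, int] = {}
    for sub in stratified_folds(dataset, k, seed):
        res = analyze(sub, **params)
        pos, neg = _pad_ids(res.records)
        per_fold.append((len(res.index), len(res.secs), len(pos), len(neg)))
        for v in pos:
            seen_pos[v] = seen_pos.get(v, 0) + 1
        for v in neg:
            seen_neg[v] = seen_neg.get(v, 0) + 1

    reoccurrence: dict[str, int] = {}
    for d in (seen_pos, seen_neg):
        for v, c in d.items():
            reoccurrence[v] = max(reoccurrence.get(v, 0), c)

    def cumulative(counts: dict[str, int]) -> dict[int, int]:
        return {m: sum(1 for c in counts.values() if c >= m) for m in range(1, k + 1)}

    return StabilityReport(
        n_folds=k,
        per_fold=per_fold,
        reoccurrence=reoccurrence,
        reoccurrence_pos=seen_pos,
        reoccurrence_neg=seen_neg,
        cumulative=cumulative(reoccurrence),
        cumulative_pos=cumulative(seen_pos),
        cumulative_neg=cumulative(seen_neg),
        chance_curve={m: chance_reoccurrence(k, m) for m in range(1, k + 1)},
    )
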