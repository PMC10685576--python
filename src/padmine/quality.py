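"""Pattern quality, sibling statistics and Pharmacophore Activity Delta.

The default quality of a pattern is the normalized growth rate.  With the
molecule set split into actives and inactives, the growth rate is the
ratio of the pattern's fit frequencies,

    GR = (hits_active / n_active) / (hits_inactive / n_inactive)

and its normalization GR_N = GR / (GR + 1) lies in [0, 1]: 0.5 means
equal frequency in both classes, 1 an actives-only pattern, 0 an
inactives-only pattern (GR = 3 maps to 0.75).

A vertex v of a pharmacophore (or EC) network is a *Pharmacophore
Activity Delta* (PAD) when its quality deviates from the mean quality of
its siblings by at least δ sibling standard deviations:

    mu    = mean of f over siblings(v)
    sigma = population standard deviation of f over siblings(v)
    Pert(v) = (f(v) - mu) / sigma,   PAD  iff  |Pert(v)| >= delta

Degenerate cases (the definition is silent on them): a vertex without
siblings has undefined pertinence and is never a PAD; sigma = 0 with a
nonzero deviation gives ±inf and *is* flagged — when siblings agree
perfectly, even a small deviation stands out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .model import Dataset
from .network import PharmNetwork

__all__ = [
    "QualityResult",
    "PertinenceRecord",
    "growth_rate",
    "network_quality",
    "sibling_stats",
    "pertinence",
    "select_pads",
    "mmrfs_select",
]


@dataclass(frozen=True)
class QualityResult:
    """Growth-rate quality of one support set."""

    vertex: str | None
    n_active_hits: int
    n_inactive_hits: int
    gr: float  # may be math.inf when the pattern never hits inactives
    gr_n: float  # always finite, in [0, 1]


@dataclass(frozen=True)
class PertinenceRecord:
    """Sibling-deviation statistics for one network vertex."""

    vertex: str
    quality: float
    card_siblings: int
    mu: float | None
    sigma: float | None
    pertinence: float | None  # None when card = 0; may be ±inf
    is_pad: bool
    delta: float


def growth_rate(support: frozenset[str] | set[str], dataset: Dataset, vertex: str | None = None) -> QualityResult:
    """Growth rate and normalized growth rate of a support set.

    GR_N is computed directly from the four counts as
    ``ha*ni / (ha*ni + hi*na)`` which equals GR/(GR+1) and stays finite
    when the pattern never occurs in inactives.  Molecules without an
    activity label are ignored in the counts.
    """
    if not support:
        raise ValueError("support is empty")
    na, ni = dataset.n_active, dataset.n_inactive
    if na == 0 or ni == 0:
        raise ValueError("growth rate needs at least one active and one inactive molecule")
    ha = len(dataset.active_ids & set(support))
    hi = len(dataset.inactive_ids & set(support))
    if ha == 0 and hi == 0:
        raise ValueError("support contains no activity-labeled molecule")
    if hi == 0:
        gr = math.inf
    else:
        gr = (ha / na) / (hi / ni)
    gr_n = (ha * ni) / (ha * ni + hi * na)
    return QualityResult(vertex, ha, hi, gr, gr_n)


def network_quality(net: PharmNetwork, dataset: Dataset) -> dict[str, QualityResult]:
    """GR_N for every vertex of a network, from its support set.  Works
    identically for pharmacophore-level and EC-level networks (an EC's
    quality is the quality of its shared support)."""
    return {v: growth_rate(net.support(v), dataset, vertex=v) for v in net.vertices}


def sibling_stats(
    net: PharmNetwork, quality: Mapping[str, float], v: str
) -> tuple[float | None, float | None, int]:
    """Mean and population standard deviation of quality over siblings(v).

    Returns ``(mu, sigma, card)``; ``mu`` and ``sigma`` are None when the
    vertex has no siblings (the mean divides by the sibling count).
    The standard deviation divides by the sibling count, not count - 1.
    """
    sibs = net.siblings(v)
    card = len(sibs)
    if card == 0:
        return None, None, 0
    vals = [quality[s] for s in sorted(sibs)]
    mu = sum(vals) / card
    sigma = math.sqrt(sum((x - mu) ** 2 for x in vals) / card)
    return mu, sigma, card


def pertinence(net: PharmNetwork, quality: Mapping[str, float], v: str) -> float | None:
    """Sibling-deviation score (quality(v) - mu) / sigma.

    None when the vertex has no siblings; ±inf when sigma = 0 and the
    deviation is nonzero; 0.0 when both are zero.
    """
    mu, sigma, card = sibling_stats(net, quality, v)
    if card == 0:
        return None
    dev = quality[v] - mu
    if sigma == 0.0:
        if dev == 0.0:
            return 0.0
        return math.inf if dev > 0 else -math.inf
    return dev / sigma


def select_pads(
    net: PharmNetwork,
    quality: Mapping[str, float],
    delta: float = 1.64,
) -> list[PertinenceRecord]:
    """Pertinence records for every vertex, PAD flag set at threshold δ.

    A vertex is a PAD iff its pertinence is defined and |pertinence| ≥ δ;
    sibling-free vertices are never PADs, and ±inf pertinences always
    are.  Records are ordered by vertex id, so the output is a pure
    function of the inputs.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    out: list[PertinenceRecord] = []
    for v in net.vertices:
        mu, sigma, card = sibling_stats(net, quality, v)
        if card == 0:
            pert: float | None = None
        else:
            dev = quality[v] - mu
            if sigma == 0.0:
                pert = 0.0 if dev == 0.0 else math.copysign(math.inf, dev)
            else:
                pert = dev / sigma
        is_pad = pert is not None and abs(pert) >= delta
        out.append(
            PertinenceRecord(
                vertex=v,
                quality=quality[v],
                card_siblings=card,
                mu=mu,
                sigma=sigma,
                pertinence=pert,
                is_pad=is_pad,
                delta=delta,
            )
        )
    return out


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def mmrfs_select(
    pads: Sequence[PertinenceRecord],
    supports: Mapping[str, frozenset[str]],
    k: int | None = None,
    coverage: float | None = None,
    lam: float = 0.5,
    n_molecules: int | None = None,
) -> list[str]:
    """Greedy maximal-marginal-relevance summarization of a PAD set.

    The first pick is the PAD with the highest |pertinence|; each
    subsequent pick maximizes ``relevance - lam * max Jaccard(support,
    supports of already picked)``.  Selection stops after ``k`` picks or
    once the union of supports covers ``coverage`` (a fraction of
    ``n_molecules``).  Ties break on the notation string, so the result
    is deterministic.
    """
    if not pads:
        raise ValueError("no PADs to summarize")
    if coverage is not None and n_molecules is None:
        raise ValueError("coverage target needs n_molecules")

    def relevance(r: PertinenceRecord) -> float:
        return abs(r.pertinence) if r.pertinence is not None else 0.0

    remaining = {r.vertex: r for r in pads}
    chosen: list[str] = []
    covered: set[str] = set()
    while remaining:
        if k is not None and len(chosen) >= k:
            break
        if coverage is not None and len(covered) / n_molecules >= coverage:
            break
        best_v, best_score = None, None
        for v in sorted(remaining):
            r = remaining[v]
            red = max((_jaccard(supports[v], supports[c]) for c in chosen), default=0.0)
            score = relevance(r) - lam * red
            if best_score is None or score > best_score:
                best_v, best_score = v, score
        chosen.append(best_v)
        covered |= supports[best_v]
        del remaining[best_v]
    return chosen
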