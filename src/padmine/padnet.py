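"""PAD similarity network: molecule-level similarity, 2-NN edges, export.

PADs of different orders cannot be compared by a graph edit distance, so
the similarity between two PADs is defined at the molecule level: the
average pairwise similarity (typically ECFP4/Tanimoto) between the
molecules supporting each PAD.  The network keeps, for every PAD, the
edges to its k nearest neighbors (k = 2 by default); every neighbor tied
at the k-th similarity value is retained as well, since identical
coefficients are common.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix", "pad_similarity", "build_knn_network", "write_pad_graphml", "write_pad_sif"]


@dataclass
class SimilarityMatrix:
    """Symmetric molecule-molecule similarity with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity table must be {n}x{n}")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity table is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0, 1]")
        self._pos = {m: i for i, m in enumerate(self.ids)}

    def index_of(self, mol_id: str) -> int:
        try:
            return self._pos[mol_id]
        except KeyError:
            raise KeyError(f"molecule id {mol_id!r} not in similarity matrix") from None

    @classmethod
    def read_tsv(cls, path) -> "SimilarityMatrix":
        """Square TSV with molecule ids as header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != ids:
            raise ValueError("similarity TSV row and column ids differ")
        return cls(ids, df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def pad_similarity(
    support_a: Iterable[str], support_b: Iterable[str], sim: SimilarityMatrix
) -> float:
    """Average molecule-pair similarity between two PAD supports:
    mean of sim[m1, m2] over m1 in support(a), m2 in support(b)."""
    ia = [sim.index_of(m) for m in sorted(set(support_a))]
    ib = [sim.index_of(m) for m in sorted(set(support_b))]
    if not ia or not ib:
        raise ValueError("PAD supports must be non-empty")
    return float(sim.values[np.ix_(ia, ib)].mean())


def build_knn_network(
    pads: Mapping[str, frozenset[str]],
    sim: SimilarityMatrix,
    k: int = 2,
    attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Undirected k-nearest-neighbor network over PADs.

    ``pads`` maps PAD id -> support set.  For each PAD, the other PADs
    are ranked by descending :func:`pad_similarity`; edges to the top-k
    are kept, plus every neighbor tied at the k-th value.  Edges are
    deduplicated (an edge survives if either endpoint ranks the other);
    the result is invariant to input ordering.
    """
    if len(pads) < 2:
        raise ValueError("need at least two PADs")
    if k < 1:
        raise ValueError("k must be >= 1")
    names = sorted(pads)
    n = len(names)
    simmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = pad_similarity(pads[names[i]], pads[names[j]], sim)
            simmat[i, j] = simmat[j, i] = s
    g = nx.Graph()
    for v in names:
        g.add_node(v, **(dict(attributes.get(v, {})) if attributes else {}))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        ranked = sorted(others, key=lambda j: (-simmat[i, j], names[j]))
        if len(ranked) <= k:
            keep = ranked
        else:
            threshold = simmat[i, ranked[k - 1]]
            keep = [j for j in ranked if simmat[i, j] >= threshold]
        for j in keep:
            g.add_edge(names[i], names[j], weight=float(simmat[i, j]))
    return g


def write_pad_graphml(g: nx.Graph, path) -> None:
    """GraphML export consumable by Cytoscape."""
    nx.write_graphml(g, path)


def write_pad_sif(g: nx.Graph, path, relation: str = "similar") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for v in sorted(g.nodes):
            if g.degree(v) == 0:
                fh.write(f"{v}\n")
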