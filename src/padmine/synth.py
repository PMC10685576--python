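"""Synthetic feature-graph datasets and hand-built worked-example fixtures.

Two kinds of test material live here:

* small hand-built support indexes whose network structure (edges,
  parents, siblings, equivalence-class groupings) is known exactly, and
* :func:`generate`, a seeded generator of activity-labeled molecule
  feature graphs with *planted* class-discriminative pharmacophores.

Generated molecules draw their pharmacophoric feature points on random
trees so the distance tables are genuine shortest-path metrics; a
planted pattern is embedded verbatim as an extra feature block bridged
to the molecule skeleton by a long edge, which preserves the metric and
keeps the planted distances exact.  Activity labels are assigned so the
planted pattern's empirical normalized growth rate lands on its target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .mining import SupportIndex
from .model import Dataset, MoleculeRecord, Pharmacophore, parse_notation
from .network import PharmNetwork, build_network

__all__ = [
    "PlantSpec",
    "WorkedExampleExpected",
    "worked_example_fixture",
    "sibling_example_fixture",
    "generate",
    "sibling_family_plants",
    "shuffle_labels",
]

#: minimum bridge length between a planted feature block and the noise
#: skeleton; long enough that no shortest path shortcuts through it.  The
#: actual length varies per molecule so that plant-to-skeleton distances
#: do not align across carriers (carriers share the motif, not the
#: scaffold) and no frequent cross-block pattern is created.
_BRIDGE = 25


@dataclass(frozen=True)
class PlantSpec:
    """One pattern to embed into a fraction of the generated molecules.

    ``target_gr_n`` is the normalized growth rate the pattern's support
    should exhibit once activity labels are assigned; ``carrier_fraction``
    is the fraction of molecules embedding the pattern.  The pattern's
    distances must satisfy the triangle inequality (a bond-path metric
    always does), otherwise a verbatim embedding is impossible.
    """

    pattern: Pharmacophore
    target_gr_n: float
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_gr_n <= 1.0:
            raise ValueError("target_gr_n must lie in [0, 1]")
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in (0, 1]")
        p = self.pattern
        for i, j, k in itertools.permutations(range(p.order), 3):
            if p.distance(i, j) > p.distance(i, k) + p.distance(k, j):
                raise ValueError(
                    f"pattern {p.notation} violates the triangle inequality; "
                    "it cannot be realized as a bond-path metric"
                )


# ---------------------------------------------------------------------------
# hand-built fixtures


def _support_index(rows: list[tuple[str, set[str]]], min_support: int = 1) -> SupportIndex:
    entries = {}
    max_order = 1
    for notation, supp in rows:
        p = parse_notation(notation)
        entries[p.notation] = (p, frozenset(supp))
        max_order = max(max_order, p.order)
    return SupportIndex(entries, min_support, max_order, None)


@dataclass(frozen=True)
class WorkedExampleExpected:
    """Expected structure of the six-molecule worked example."""

    edges: frozenset[tuple[str, str]]
    gecs: frozenset[frozenset[str]]
    decs: frozenset[frozenset[str]]
    secs: frozenset[frozenset[str]]


def worked_example_fixture() -> tuple[SupportIndex, PharmNetwork, WorkedExampleExpected]:
    """Six-molecule worked example with known network and EC structure.

    Patterns over molecules M1..M6:

    * three order-1 patterns A, D, N supported by all six molecules —
      one GEC that splits into three singleton SECs;
    * order-2 patterns AN, AD, DN supported by {M1, M2} — one GEC and
      DEC, three singleton SECs (no edges inside the class);
    * order-3/4 patterns ADN, ARN, DNR, ADRN supported by {M2} — one
      GEC forming a single SEC (ADRN connects the three order-3
      members) and two DECs;
    * DR and ADR supported by {M3, M4, M5, M6} — one GEC, one SEC, two
      DECs.

    AN is a subgraph of ARN and ADN, so its vertex is connected to
    theirs, and their supports are subsets of AN's.

    Returns the support index, the expected Hasse diagram (built from
    the literal edge list, not via :func:`build_network`), and the
    expected equivalence-class groupings.
    """
    all6 = {f"M{i}" for i in range(1, 7)}
    m12 = {"M1", "M2"}
    m2 = {"M2"}
    m3456 = {"M3", "M4", "M5", "M6"}
    rows = [
        ("|A|", all6),
        ("|D|", all6),
        ("|N|", all6),
        ("|A|N| |2|", m12),
        ("|A|D| |3|", m12),
        ("|D|N| |1|", m12),
        ("|A|D|N| |3|2|1|", m2),
        ("|A|N|R| |2|1|1|", m2),
        ("|D|N|R| |1|2|1|", m2),
        ("|A|D|N|R| |3|2|1|1|2|1|", m2),
        ("|D|R| |4|", m3456),
        ("|A|D|R| |5|2|4|", m3456),
    ]
    index = _support_index(rows)

    edges = frozenset(
        {
            ("|A|", "|A|N| |2|"),
            ("|A|", "|A|D| |3|"),
            ("|A|", "|A|D|R| |5|2|4|"),
            ("|D|", "|A|D| |3|"),
            ("|D|", "|D|N| |1|"),
            ("|D|", "|D|R| |4|"),
            ("|N|", "|A|N| |2|"),
            ("|N|", "|D|N| |1|"),
            ("|A|N| |2|", "|A|D|N| |3|2|1|"),
            ("|A|N| |2|", "|A|N|R| |2|1|1|"),
            ("|A|D| |3|", "|A|D|N| |3|2|1|"),
            ("|D|N| |1|", "|A|D|N| |3|2|1|"),
            ("|D|N| |1|", "|D|N|R| |1|2|1|"),
            ("|D|R| |4|", "|A|D|R| |5|2|4|"),
            ("|A|D|N| |3|2|1|", "|A|D|N|R| |3|2|1|1|2|1|"),
            ("|A|N|R| |2|1|1|", "|A|D|N|R| |3|2|1|1|2|1|"),
            ("|D|N|R| |1|2|1|", "|A|D|N|R| |3|2|1|1|2|1|"),
        }
    )
    expected_net = PharmNetwork()
    for key, (p, supp) in index.entries.items():
        expected_net.add_vertex(key, p, supp)
    for u, v in edges:
        expected_net.add_edge(u, v)

    f = frozenset
    grey = f({"|A|", "|D|", "|N|"})
    blue = f({"|A|N| |2|", "|A|D| |3|", "|D|N| |1|"})
    purple3 = f({"|A|D|N| |3|2|1|", "|A|N|R| |2|1|1|", "|D|N|R| |1|2|1|"})
    purple = purple3 | f({"|A|D|N|R| |3|2|1|1|2|1|"})
    orange = f({"|D|R| |4|", "|A|D|R| |5|2|4|"})
    expected = WorkedExampleExpected(
        edges=edges,
        gecs=f({grey, blue, purple, orange}),
        decs=f(
            {
                grey,
                blue,
                purple3,
                f({"|A|D|N|R| |3|2|1|1|2|1|"}),
                f({"|D|R| |4|"}),
                f({"|A|D|R| |5|2|4|"}),
            }
        ),
        secs=f(
            {
                f({"|A|"}),
                f({"|D|"}),
                f({"|N|"}),
                f({"|A|N| |2|"}),
                f({"|A|D| |3|"}),
                f({"|D|N| |1|"}),
                purple,
                orange,
            }
        ),
    )
    return index, expected_net, expected


def sibling_example_fixture() -> tuple[PharmNetwork, str, frozenset[str]]:
    """Sibling worked example: origin ADR with parents AD, AR, DR and six
    siblings ARP, DRP, ADP, ARN, DRN, ADN.

    All patterns share the pairwise distances d(A,D)=1, d(A,R)=2,
    d(D,R)=3, d(X to its pair partners)=1,2 so each order-3 child covers
    exactly one order-2 parent from {AD, AR, DR}... the origin covers all
    three.  Returns (network, origin vertex id, expected sibling ids).
    """
    m_all = {"M1", "M2", "M3", "M4"}
    child_sup = {"M1"}
    rows: list[tuple[str, set[str]]] = [
        ("|A|D| |1|", m_all),
        ("|A|R| |2|", m_all),
        ("|D|R| |3|", m_all),
        ("|A|D|R| |1|2|3|", child_sup),  # origin: contains AD, AR and DR
        ("|A|P|R| |1|2|1|", child_sup),  # contains AR
        ("|D|P|R| |1|3|1|", child_sup),  # contains DR
        ("|A|D|P| |1|2|2|", child_sup),  # contains AD
        ("|A|N|R| |1|2|1|", child_sup),  # contains AR
        ("|D|N|R| |1|3|1|", child_sup),  # contains DR
        ("|A|D|N| |1|2|2|", child_sup),  # contains AD
    ]
    index = _support_index(rows)
    net = build_network(index)
    origin = "|A|D|R| |1|2|3|"
    siblings = frozenset(
        {
            "|A|P|R| |1|2|1|",
            "|D|P|R| |1|3|1|",
            "|A|D|P| |1|2|2|",
            "|A|N|R| |1|2|1|",
            "|D|N|R| |1|3|1|",
            "|A|D|N| |1|2|2|",
        }
    )
    return net, origin, siblings


# ---------------------------------------------------------------------------
# generator


def _random_tree_distances(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """All-pairs hop distances on a random attachment tree."""
    parent = [0] * n_nodes
    for v in range(1, n_nodes):
        parent[v] = int(rng.integers(0, v))
    dist = np.zeros((n_nodes, n_nodes), dtype=int)
    # depth-first accumulation: distance via parent chain
    for v in range(1, n_nodes):
        p = parent[v]
        for u in range(v):
            dist[v][u] = dist[u][v] = dist[u][p] + 1
    return dist


def _build_molecule(
    mol_id: str,
    n_noise: int,
    plant: Pharmacophore | None,
    rng: np.random.Generator,
) -> MoleculeRecord:
    from .model import FEATURE_CODES

    # skeletons carry more atoms than feature points, as drug-sized
    # molecules do; the resulting bond distances spread over ~1-15 bonds
    n_skeleton = n_noise + int(rng.integers(4, 13))
    tree = _random_tree_distances(n_skeleton, rng)
    anchors = rng.choice(n_skeleton, size=n_noise, replace=False)
    kinds = [FEATURE_CODES[i] for i in rng.integers(0, len(FEATURE_CODES), n_noise)]
    features: list[tuple[str, int]] = []
    seen = set()
    for kind, a in zip(kinds, anchors):
        if (kind, int(a)) not in seen:
            seen.add((kind, int(a)))
            features.append((kind, int(a)))
    n_f = len(features)

    if plant is None:
        dist = [
            [int(tree[features[i][1]][features[j][1]]) for j in range(n_f)]
            for i in range(n_f)
        ]
        return MoleculeRecord(mol_id, tuple(features), tuple(map(tuple, dist)))

    # planted block: extra anchor points beyond the skeleton, bridged to
    # skeleton node 0 through a long edge of per-molecule random length so
    # the metric is preserved and the planted pairwise distances stay exact
    bridge = _BRIDGE + int(rng.integers(0, 30))
    k = plant.order
    total = n_f + k
    dist_full: list[list[int]] = [[0] * total for _ in range(total)]
    for i in range(n_f):
        for j in range(n_f):
            dist_full[i][j] = int(tree[features[i][1]][features[j][1]])
    for a in range(k):
        for b in range(k):
            dist_full[n_f + a][n_f + b] = plant.distance(a, b)
    # cross distances: through the bridge (plant vertex 0 <-> skeleton node 0)
    for i in range(n_f):
        d_i0 = int(tree[features[i][1]][0])
        for a in range(k):
            d = d_i0 + bridge + plant.distance(0, a)
            dist_full[i][n_f + a] = dist_full[n_f + a][i] = d
    plant_features = [
        (plant.labels[a], 1000 + a) for a in range(k)
    ]  # anchor ids offset so they never collide with skeleton nodes
    all_features = tuple(features) + tuple(plant_features)
    return MoleculeRecord(mol_id, all_features, tuple(map(tuple, dist_full)))


def _assign_activity(
    n: int,
    carrier_sets: list[list[int]],
    targets: list[float],
    rng: np.random.Generator,
) -> list[bool]:
    """Activity flags per molecule index: non-carriers Bernoulli(0.5);
    within each plant's carriers the number of actives is chosen so the
    plant's empirical GR_N is as close as possible to its target."""
    is_carrier = [False] * n
    for cs in carrier_sets:
        for i in cs:
            is_carrier[i] = True
    non_carriers = [i for i in range(n) if not is_carrier[i]]
    active = [False] * n
    for i in non_carriers:
        active[i] = bool(rng.random() < 0.5)

    # actives among each carrier set: start at the naive proportion, then
    # refine coordinate-wise against the empirical GR_N
    ks = [round(t * len(cs)) for t, cs in zip(targets, carrier_sets)]
    base_active = sum(active[i] for i in non_carriers)
    base_inactive = len(non_carriers) - base_active

    def gr_n(k_i: int, n_ci: int, na: int, ni: int) -> float:
        ha, hi = k_i, n_ci - k_i
        denom = ha * ni + hi * na
        return 0.5 if denom == 0 else (ha * ni) / denom

    for _ in range(4):
        for idx, (t, cs) in enumerate(zip(targets, carrier_sets)):
            na = base_active + sum(ks)
            ni = base_inactive + sum(len(c) for c in carrier_sets) - sum(ks)
            best_k, best_err = ks[idx], None
            for k_i in range(len(cs) + 1):
                na_i = na - ks[idx] + k_i
                ni_i = ni + ks[idx] - k_i
                if na_i == 0 or ni_i == 0:
                    continue
                err = abs(gr_n(k_i, len(cs), na_i, ni_i) - t)
                if best_err is None or err < best_err:
                    best_k, best_err = k_i, err
            if best_err is None:
                raise ValueError("cannot achieve any growth rate: one class would be empty")
            # GR_N is only adjustable in ~1/|carriers| steps; beyond that
            # resolution the target is genuinely unreachable
            if best_err > max(0.1, 1.5 / len(cs)):
                raise ValueError(
                    f"target_gr_n {t} infeasible for {len(cs)} carriers "
                    f"(best achievable error {best_err:.3f})"
                )
            ks[idx] = best_k

    for k_i, cs in zip(ks, carrier_sets):
        order = list(cs)
        rng.shuffle(order)
        for j, i in enumerate(order):
            active[i] = j < k_i
    return active


def generate(
    n_molecules: int,
    plants: list[PlantSpec],
    seed: int,
    noise_features: tuple[int, int] = (4, 8),
    activity_cutoff: float = 100.0,
) -> Dataset:
    """Generate an activity-labeled feature-graph dataset with planted
    discriminative pharmacophores.

    Every molecule gets ``noise_features`` random feature points (kinds
    uniform over the six codes) anchored on a random tree, so distance
    tables are exact shortest-path metrics.  Plant carrier subsets are
    disjoint; each carrier embeds its plant's pattern verbatim.  Labels:
    non-carriers are active with probability 1/2; within each plant's
    carriers the active count is tuned so the plant's empirical GR_N
    matches its target.  Fully deterministic per seed.
    """
    if n_molecules < 10:
        raise ValueError("n_molecules must be >= 10")
    if sum(p.carrier_fraction for p in plants) > 1.0 + 1e-9:
        raise ValueError("carrier fractions sum to more than 1")
    lo, hi = noise_features
    if not 1 <= lo <= hi:
        raise ValueError("noise_features must be a (low, high) range with low >= 1")
    rng = np.random.default_rng(seed)

    order = list(range(n_molecules))
    rng.shuffle(order)
    carrier_sets: list[list[int]] = []
    cursor = 0
    for spec in plants:
        n_c = round(spec.carrier_fraction * n_molecules)
        if n_c == 0:
            raise ValueError(
                f"carrier_fraction {spec.carrier_fraction} yields no carriers"
            )
        carrier_sets.append(sorted(order[cursor : cursor + n_c]))
        cursor += n_c

    plant_of: dict[int, Pharmacophore] = {}
    for spec, cs in zip(plants, carrier_sets):
        for i in cs:
            plant_of[i] = spec.pattern

    molecules = []
    active = _assign_activity(
        n_molecules, carrier_sets, [p.target_gr_n for p in plants], rng
    )
    width = len(str(n_molecules - 1))
    for i in range(n_molecules):
        n_noise = int(rng.integers(lo, hi + 1))
        mol = _build_molecule(f"S{i:0{width}d}", n_noise, plant_of.get(i), rng)
        value = (
            float(rng.uniform(1.0, activity_cutoff))
            if active[i]
            else float(rng.uniform(activity_cutoff * 1.01, activity_cutoff * 100))
        )
        molecules.append(
            MoleculeRecord(mol.id, mol.features, mol.dist, activity_value=value)
        )
    return Dataset(molecules, activity_cutoff)


def sibling_family_plants(
    target: float = 0.95,
    n_null_siblings: int = 4,
    outlier_fraction: float = 0.15,
    null_fraction: float = 0.12,
) -> list[PlantSpec]:
    """A plant family producing one outlier among null siblings.

    All members share the order-2 sub-pattern |A|D| |2|, so once mined
    they are children of the same parent and hence siblings in the Hasse
    diagram.  The first plant carries the discriminative signal
    (``target``); the others sit at GR_N 0.5.  Distances are chosen
    large enough (5-6 bonds) that chance co-occurrence in the random
    skeletons is rare.
    """
    family = [
        "|A|D|R| |2|6|6|",  # the outlier
        "|A|D|H| |2|6|6|",
        "|A|D|N| |2|6|6|",
        "|A|D|P| |2|6|6|",
        "|A|D|R| |2|5|5|",
        "|A|D|H| |2|5|5|",
    ]
    if not 1 <= n_null_siblings <= len(family) - 1:
        raise ValueError(f"n_null_siblings must be in [1, {len(family) - 1}]")
    plants = [PlantSpec(parse_notation(family[0]), target, outlier_fraction)]
    for notation in family[1 : 1 + n_null_siblings]:
        plants.append(PlantSpec(parse_notation(notation), 0.5, null_fraction))
    return plants


def shuffle_labels(dataset: Dataset, seed: int) -> Dataset:
    """Null model: the same molecules with activity values permuted.

    Destroys every pattern-activity association while keeping supports,
    class sizes and the network identical.
    """
    rng = np.random.default_rng(seed)
    values = [m.activity_value for m in dataset]
    perm = rng.permutation(len(values))
    molecules = [
        MoleculeRecord(m.id, m.features, m.dist, activity_value=values[perm[i]])
        for i, m in enumerate(dataset)
    ]
    return Dataset(molecules, dataset.activity_cutoff)
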