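# Methods

## Pattern model and notation

A topological pharmacophore of order *k* is a complete graph on *k*
vertices labeled with feature codes from {A, D, H, N, P, R} and with
edge labels equal to shortest bond-path lengths (integers ≥ 0).  The
pipe notation stores the label sequence followed by the
`k(k−1)/2` distances in row-major upper-triangle order (first feature
against all later ones, then the second, and so on).

Identity is defined on **canonical forms**: the vertex permutation
minimizing the `(labels, distances)` pair lexicographically, with the
feature codes ordered alphabetically (A < D < H < N < P < R).  Only
permutations that keep the label sequence sorted can be minimal, so
canonicalization searches the product of permutations within equal-label
blocks (worst case `k!` when all labels coincide; `k ≤ 7` keeps this
trivial).  The canonical notation string is the dictionary key used
everywhere downstream, which makes every artifact byte-reproducible.

`p ⊆ q` holds iff an injective vertex map preserves labels and *exact*
distances; the test is a backtracking search over label-compatible
images with incremental distance checks.  On canonical forms ⊆ is a
partial order (checked property-wise and against an exhaustive
injection oracle in the tests).

Molecules are feature graphs: (code, anchor) points plus a symmetric
distance table.  Multi-atom features are anchored at a single
deterministic atom (lowest index in the RDKit feature's atom set) so
distances stay integral and reproducible; the anchor rule is this
package's convention, since bond-count distances between extended
features are otherwise ambiguous.  Feature pairs on different fragments
have no bond path; their distance is a `None` sentinel and such pairs
are never co-embedded.  Duplicate (code, anchor) pairs are rejected at
construction.

## Mining

Extraction is level-wise: order-1 patterns come from the feature points;
an order-(k+1) candidate arises only by extending a *witness embedding*
(a feature-index subset) of a frequent order-k pattern by one more
reachable feature point.  Because support is anti-monotone under ⊆,
pruning below `min_support` at each level is sound, and every frequent
(k+1)-subset contains a frequent k-sub-witness, so the enumeration is
complete (verified against per-molecule exhaustive enumeration on small
sets).  Witness sets are internal; the public contract is the canonical
pattern → support-set index.  Defaults mirror common practice for
activity-labeled sets: `min_support = 10`, orders 1–7, activity cutoff
100 nM.  The absolute pattern counts of any given published corpus are
not reproducible without that corpus's exact feature definitions; only
structural invariants are asserted.

## Hasse diagram

Strict containments are computed pairwise with three prunes (order,
support inclusion, label-multiset inclusion) before the exact subgraph
test; cover edges keep `(u, v)` iff no third vertex lies strictly
between.  The tests compare this against an independent route
(networkx `transitive_reduction` over the brute-force containment
matrix).  Cover edges may span more than one order when intermediate
patterns fall below the support threshold — the cover condition
quantifies only over mined vertices.

**Siblings.**  `S(p)` = vertices sharing at least one Hasse parent with
`p`, *excluding `p` itself*.  The set-builder definition of the sibling
set literally admits the origin vertex; we exclude it because a
self-inclusive mean would pull the sibling mean toward the origin's own
quality and shrink every pertinence toward zero.  This is a deliberate,
documented divergence risk.

## Equivalence classes

GEC groups vertices by frozen support set; DEC refines by order; SEC
refines by connectivity inside the class, treating Hasse edges as
undirected (the underlying adjacency relation is symmetric, so a path
may ascend and descend).  Generators/closed members are the class
members without in-class parents/children; the representative is the
lexicographically smallest generator, and an EC is booked under its
representative's order in distribution reports.  The condensed EC
network lifts the edge relation (EC1 < EC2 iff a member edge crosses),
transitively closes it, and reduces to cover edges with the same
machinery as the pattern-level network.  Within one GEC, distinct SECs
are never linked by a member edge (such an edge would merge them), so
the lifted relation is acyclic.

## Quality, pertinence, PAD

`GR_N` is computed directly from integer counts as
`ha·ni / (ha·ni + hi·na)`, which equals `GR/(GR+1)` and stays finite
for inactives-free supports.  Unlabeled molecules stay in supports but
never enter the counts.  Sibling statistics use the *population*
standard deviation (divide by the sibling count, no Bessel correction),
matching the defining formula.  Degenerate cases, on which the
definition is silent:

* no siblings → pertinence undefined, never a PAD (the mean would
  divide by zero);
* `σ = 0`, deviation ≠ 0 → pertinence `±inf`, always a PAD — when
  siblings agree perfectly, even a small deviation is interesting;
* `σ = 0`, deviation 0 → pertinence 0.

The quality function is pluggable (any vertex → real mapping); `GR_N`
is the default.  Pertinence can be evaluated on the pattern-level
network or (default) on the SEC network, where an EC's quality is the
`GR_N` of its shared support; both levels are exposed because the
sibling structure differs between them.

**MMR summarization.**  The PAD set is condensed greedily: first the
highest `|pertinence|`, then repeatedly the maximizer of
`|pertinence| − λ · max Jaccard(support, selected supports)` (λ default
0.5), stopping at `k` picks or a molecule-coverage target, ties broken
by notation.  This is a standard maximal-marginal-relevance scheme and
a declared stand-in: the original feature-selection variant is defined
elsewhere and its exact outputs are not a target.

## PAD network

PAD–PAD similarity = mean molecule-pair similarity between supports,
which is well defined across pattern orders.  The package never
computes fingerprints itself: the molecule similarity matrix is either
supplied as a square TSV or built externally (ECFP4/Tanimoto being the
conventional choice).  Each PAD retains edges to its `k = 2` most
similar PADs, and *every* neighbor tied at the k-th similarity value is
retained, since identical coefficients are common; edges are undirected
and deduplicated, so the network is invariant to input order and grows
monotonically in `k` (5 and 10 are exposed as options).  Node polarity
("active"/"inactive") uses a configurable `GR_N` threshold, default 0.5.

## Stability protocol

Each class (active/inactive/unlabeled) is shuffled with the seed and
dealt round-robin into `k` folds, so subsets preserve class proportions
within rounding without an external dependency; subset *i* omits fold
*i*.  `min_support` is not rescaled for the 90% subsets.  The pipeline
runs independently per subset; PAD identity across subsets is the
vertex id (canonical notation, or the representative generator notation
at SEC level).  The chance baseline `((k−2)/(k−1))^m` treats fold
overlaps as independent; it is reported as a heuristic reference
curve, not a calibrated null.

## Synthetic data

The generator emulates annotated feature graphs, not chemistry: no
SMILES, valence or ring systems.  Each molecule's skeleton is a random
attachment tree whose node count exceeds the feature count by 4–12 —
drug-sized molecules carry more atoms than feature points — giving
bond distances that spread over roughly 1–15 and keeping chance
co-occurrence of exact order-3 distance triples rare.  Distance tables
are genuine shortest-path metrics by construction.

A planted pattern is embedded verbatim as an extra feature block whose
internal distances equal the pattern (patterns must satisfy the
triangle inequality, as any bond-path metric does) and which is bridged
to the skeleton by a single long edge (25 plus a per-molecule random
0–29).  The randomized bridge is load-bearing: with a fixed length,
plant-to-skeleton distances align across carriers and spurious frequent
cross-block patterns appear as siblings of the planted pattern.
Varying it mimics the real situation — carriers share a motif, not a
scaffold — and keeps the planted family's sibling neighborhood clean.

Carrier subsets of different plants are disjoint.  Labels: non-carriers
are active with probability 1/2; within each plant's carriers the
active count is tuned coordinate-wise so the plant's empirical `GR_N`
best matches its target (resolution ~1/|carriers|; a target beyond that
resolution raises an error).  Activity values are then drawn uniformly
on the proper side of the cutoff.  Everything is a pure function of the
seed.

`sibling_family_plants` builds the standard test condition: one outlier
pattern (default target `GR_N` 0.95, 15% carriers) and several null
siblings (target 0.5, 12% carriers each), all sharing the order-2
sub-pattern `|A|D| |2|` so the mined patterns become siblings under
that common parent.  What passing tests on this material shows: the
funnel recovers a planted discriminative arrangement against a null
sibling background, and selection behaves like a null on shuffled
labels.  What it does not show: behaviour under real feature-definition
noise, correlated scaffolds, or activity-cliff structure of actual
chemical series.

## Problem sizes and numerics

Tests and the acceptance script run the funnel on 120–200 molecules
with orders ≤ 3–4 and `min_support` 8–10, and cross-check oracles on
50 instances of 25–40 molecules — sizes chosen so the exhaustive
oracles (factorial canonicalization, injection enumeration, quadratic
reductions) stay feasible while the mined networks (≈ 30–200 vertices)
still exercise every code path.  All comparisons on `GR_N` and
pertinence are exact or at standard float tolerances; no numerical
optimization is involved anywhere, so results are bit-reproducible per
seed across platforms.

## Known limitations

* Mining is single-threaded and in-memory; heavily functionalized
  molecules (≥ 20 feature points) make high orders expensive, which is
  the known combinatorial pain point of this pattern domain.
* The SMILES featurizer inherits RDKit's feature definitions; published
  pattern counts obtained with other definitions will not reproduce.
* The EC-network equivalence to the pattern-level network is checked
  empirically (support-inclusion preservation), not proven.
* `chance_reoccurrence` is an upper-bound heuristic, not a null model.
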