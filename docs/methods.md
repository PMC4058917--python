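# Methods

## Model

A reconciliation instance is a rooted binary species (host) tree *S*, a
rooted binary gene (parasite) tree *T*, and a total tip association
L: Le(T) → Le(S) (many-to-one allowed).  Trees are purely topological;
branch lengths are parsed and discarded.  A **DTL-scenario** is a node
mapping M: V(T) → V(S) together with a partition of the internal gene nodes
into speciations Σ, duplications Δ and transfers Θ, transfer edges Ξ and
recipients τ, subject to the usual consistency constraints: leaves follow L;
M never maps a node strictly below a child's image; at least one child image
of every internal node is a descendant of its own image; an edge is a
transfer edge exactly when its endpoint images are incomparable; a
speciation requires incomparable child images whose LCA is the node's image;
a duplication requires the image to be an ancestor of that LCA; a transfer
recipient must be incomparable to the donor and an ancestor of the
transferred child's image.  Losses are not labelled; they are implied by the
mapping: a lineage that enters a species branch and survives only in one
child pays one loss per bypassed sibling branch (speciations discount one
edge per side since both sides must descend).

Time-consistency across transfers is deliberately **not** enforced —
requiring it makes optimization NP-hard — so a reported scenario can in rare
cases imply contradictory orderings of internal species nodes.

### Event identity

Events use the most-specific identity: speciations and duplications are
(gene node, species node); transfers additionally carry the recipient
species node and the gene child on the transfer edge; losses are a (gene
edge, species edge) pair, recorded as the surviving gene child, the species
node passed, and the sibling branch in which the lineage is absent.
Relaxed identities (mapping-only, or kind + mapping) are available via
`Event.relaxed` for analyses that do not distinguish recipients or loss
branches.

### Transfer recipients

The recipient of a transfer is canonically the species node the transferred
child maps to.  The definition admits any incomparable ancestor of that
node, but every non-canonical recipient adds the recipient-to-image distance
in losses and changes nothing else, so such scenarios are strictly dominated
and are excluded from scenario identity, counting and the front.  (The
simulator's ground-truth scenarios are the one place non-canonical
recipients appear, because there the actual landing site is known; the
validator accepts them.)

### Dual-eligible nodes

The speciation and duplication constraints are "only if" conditions: a node
whose children's images are incomparable with image equal to their LCA may
be labelled either way.  Both labelings are counted as distinct scenarios,
by the enumeration oracle and the dynamic program alike (the DP computes the
speciation and duplication tables separately and lets ⊕ add their counts).
Pareto domination removes the duplication labelling from the front itself —
it costs one duplication more at identical transfer/loss counts — so the
choice affects counts, not vectors.

## The Pareto front

P(t, s) — the antichain of Pareto-optimal vectors for reconciling T(t) with
S with t mapped to s — is built by a nested post-order traversal using two
operations on annotated antichains:

* **⊕** unions two fronts and filters; when the same vector arrives from
  both sides its counts add and its common-event sets intersect.  The empty
  front (infeasibility) is the identity.  Infeasible cells are represented
  by absence; there is no infinity arithmetic anywhere.
* **⊗** sums vectors over the Cartesian product and filters; each pair
  multiplies counts and unions events, pairs with equal sums then merge as
  in ⊕.  The implementation inserts each sum into a lexicographically
  sorted working list, resolving it immediately against its (δ, θ) column
  neighbours, so the list never holds more than one entry per column; a
  final sweep removes cross-column dominated vectors.  The empty front is
  absorbing.

Speciation combines the children's `in` tables across the two species
subtrees (in(t, s) = best over T(t) mapped at-or-below s, paying one loss
per level); duplication combines both children's `in` at s itself; transfer
combines one child's `in` at s with the other child's `out` at s (`out`
aggregating P over all species nodes incomparable to s — transfers into the
species root are impossible since nothing is incomparable to it).  Events
are attached at creation time: the speciation/duplication event when the
corresponding table entry forms, each loss event inside the `in` recurrence
(which knows the bypassed sibling branch), and each transfer event inside
`out` (which knows the recipient).  The final front is the ⊕ over all s of
P(root(T), s).

`out` is computed for every gene node, leaves included, immediately after
its `in` tables exist — the transfer recurrence consumes `out` at children,
which may be leaves.  Without event tracking `out` uses the pre-order
sibling recurrence (amortized O(1) per cell); with event tracking it is
assembled directly from P so the recipient-specific transfer event can be
attached as each contribution flows in (O(n) per cell).  Both paths produce
identical vectors and counts, and the tests assert it.

Counts and events are optional annotations; disabling them changes nothing
about the vector set.  Counting is exact even though the number of
reconciliations can grow exponentially — Python integers are unbounded.

## Cost-space partition

With duplication normalized to 1, vector v = ⟨δ, θ, ℓ⟩ costs
δ + C_T·θ + C_L·ℓ.  R(v) is the user box intersected with one closed
half-plane per competing front vector, computed by Sutherland–Hodgman
clipping of the box polygon.  All coordinates are `fractions.Fraction`:
half-plane coefficients are integer differences of event counts, so every
vertex is rational and region dimension (2 / 1 / 0) is decided by exact
collinearity tests, never by a floating-point epsilon.  Zero-area regions
are reported as first-class regions — they carry reconciliations that no
finite sampling of cost points can discover.  Regions are closed, so
boundary points belong to every touching region and `locate_point` returns
the full tie set there.  Areas come from the shoelace formula on rational
vertices; the dimension-2 areas of a partition sum exactly to the box area.
Output regions are sorted by area descending (the legend order), then by
vector, making runs byte-stable.

A 3-D (un-normalized) partition over all three costs is out of scope.

## Event consensus

Within a region, every interior cost point has the same optimal vector, so
the events common to every optimal reconciliation in the region are exactly
the front annotation of its vector.  Consensus support of an event is the
fraction of regions in which it is common to all optima (zero-area regions
count as full regions) or, under the area measure, the fraction of box area
those regions cover (zero-area regions contribute nothing).  Support
denominators include every non-empty region in the box.  The set of events
at support ≥ s is non-increasing in s under both measures.

## Permutation significance

The null for cophylogenies — host and parasite trees agree by chance — is
simulated by permuting the tip association: `shuffle` (default) permutes the
observed species targets among the gene leaves, preserving how many
parasite tips each host carries; `uniform` reassigns every gene leaf
uniformly.  For each of N permutations one Pareto front is computed; at each
cell centre of a grid over the box the p-value is (1 + r)/(N + 1), r the
number of permutations whose optimum is at most the observed optimum —
the add-one estimator, exact-rational and never zero.  Because the
fixed-cost optimum at any positive point lies on the front, one front per
permutation serves every cell, and p-values are piecewise constant over the
arrangement of the joint fronts: refining the grid never changes the value
at a fixed interior point.  A per-cell brute-force engine
(`engine="fixed"`) consumes the identical permutation stream and exists as
a cross-check on tiny instances.  Defaults are a 100×100 grid and N = 1000
permutations; the summary reports the cell fractions with p < 0.01,
0.01 ≤ p < 0.05 and p ≥ 0.05.

## Synthetic data

The simulator grows a uniform random binary species topology (random join
order), then evolves a gene lineage tip-ward.  On arrival at a species node
a lineage duplicates in place, transfers (one copy stays, one re-arrives at
a uniformly chosen incomparable node), suffers a loss (at internal nodes
only: the lineage follows a single child), or co-diverges; at species
leaves it becomes an extant gene.  Default per-arrival probabilities are
0.1/0.1/0.1 — low enough that histories stay sparse and diverse, high
enough that most instances contain each event kind.  Because losses prune
single branches and never kill whole subtrees, every simulated gene node
keeps both children, so the recorded history replays directly into a valid
DTL-scenario with no contraction step; its recipients are the actual
landing sites, making the recorded loss count equal the scenario's implied
losses.  Instances whose gene tree has fewer than two leaves, or that
exceed a node budget (default 500, guarding against runaway duplication
chains), are rejected and resampled under one seeded RNG, so results are
byte-identical per seed.

The simulator intentionally omits dated nodes, rate heterogeneity across
branches, gene conversion and incomplete lineage sorting.  Passing tests
therefore demonstrate algorithmic correctness on topologically realistic
tanglegrams, not calibration against any real clade's event rates.  Its
one guarantee used by the tests is a parsimony bound: the generating
history is a valid scenario, so the front's minimum cost at any positive
costs is at most the true history's cost.

## Numerical and design choices

* All cost comparisons, geometry and p-values are exact rationals; floats
  appear only in plots and human-readable summaries.  Float inputs for
  costs are interpreted via their decimal literal (0.1 → 1/10).
* Newick parsing is delegated to dendropy (underscores preserved); strictly
  binary trees only, duplicate leaf labels rejected, a redundant unary
  wrapper above the root collapsed, any other unary node an error.
  Internal nodes are auto-named `<min leaf of left>+<min leaf of right>`,
  which is unique and stable across runs.
* The exhaustive oracle refuses instances above 6 leaves per tree; it is
  quadratic-exponential and exists to check the polynomial algorithm, not
  to replace it.
* Test problem sizes (tanglegrams of 2–8 species, permutation counts of
  tens) are chosen so the whole suite exercises every oracle comparison in
  a few seconds; the algorithms themselves handle hundred-taxon trees in
  well under a minute.

## Known limitations

* Reported optima may be time-inconsistent (see above); no dated-tree mode.
* Counting treats the two labelings of a dual-eligible node as distinct
  scenarios; analyses that consider them the same reconciliation should
  interpret counts as upper bounds in that convention.
* The area measure of consensus support depends on the chosen box, as does
  the number of regions; support values are only comparable across runs
  with the same box.
* Whole-reconciliation consensus (beyond per-event support) is not
  implemented.
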