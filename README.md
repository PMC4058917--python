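# dtlscape

Pareto-optimal duplication–transfer–loss (DTL) reconciliation across the
whole event-cost space, for gene-tree/species-tree, parasite/host and
biogeographic tanglegram analyses.

## The problem

Maximum-parsimony reconciliation maps a gene (parasite) tree *T* into a
species (host) tree *S*, explaining their incongruence by duplications,
transfers (host switches) and losses; speciation is the free null event.
Every analysis must pick positive costs C<sub>Δ</sub> (duplication),
C<sub>Θ</sub> (transfer) and C<sub>L</sub> (loss), and the inferred events
can change qualitatively with the choice — yet there is no principled way to
pick them.  `dtlscape` sidesteps the choice: instead of one optimum at one
cost setting, it characterizes the *whole* solution space.

An **event count vector** ⟨δ, θ, ℓ⟩ records the number of duplications,
transfers and losses of a reconciliation (speciations are implicit:
m − δ − θ − 1 for a gene tree with m leaves).  A vector is **Pareto-optimal**
when no reconciliation beats it componentwise.  Normalizing C<sub>Δ</sub> = 1,
the cost of a vector at a point (C<sub>Θ</sub>, C<sub>L</sub>) is the affine
function δ + C<sub>Θ</sub>·θ + C<sub>L</sub>·ℓ, so each Pareto vector *v* is
optimal on a convex **region**
R(v) = { (C<sub>Θ</sub>, C<sub>L</sub>) : cost(v) ≤ cost(v′) ∀v′ } —
possibly a polygon, a line segment or a single point.  The regions tile the
user's cost box and answer, exactly: *which reconciliations are optimal
where, and how robust is each inferred event to the cost choice?*

## What the package computes

* **Pareto front** (`pareto_reconcile`): all Pareto-optimal event count
  vectors, by a nested post-order dynamic program over (gene node, species
  node) cells whose entries are antichains of vectors, merged with two
  operations — ⊕ (union + Pareto filter) and ⊗ (Cartesian sums + Pareto
  filter, maintained one-vector-per-(δ,θ) in a lexicographically sorted
  list).  Each front vector optionally carries the number of distinct
  reconciliations achieving it and the set of events common to all of them.
* **Cost-space partition** (`partition_regions`, the *costscape* analysis):
  each front vector's region as an exact convex polygon — every vertex a
  pair of `fractions.Fraction`s — with exact area and dimension (2, 1 or 0).
  Zero-area regions are real solutions that no sampling of cost points can
  find; exact arithmetic is what makes them decidable.
* **Event consensus** (`events_consensus`, the *eventscape* analysis): the
  events common to every optimal reconciliation per region, their partition
  by how many regions share them, and consensus support — the fraction of
  regions (or of cost-space area) in which an event is common to all optima.
* **Permutation significance** (`significance_grid`, the *sigscape*
  analysis): for cophylogenies, the null "the trees match by chance" is
  tested by permuting tip associations; p = (1+r)/(N+1) per grid cell over
  the cost box, with one Pareto front per permutation serving every cell.
* **Synthetic instances** (`synthetic`): the minimal 3-leaf worked
  tanglegram and a cophylogeny simulator that records its generating history
  as a replayable, provably valid DTL-scenario.

Exhaustive scenario enumeration and brute-force fixed-cost optimization
(`enumerate_scenarios`, `min_cost_fixed(..., method="enumerate")`) are
included as independent oracles and power the test suite.

## Worked example

The smallest instance with a genuine trade-off: species tree `((A,B),C);`,
gene tree `(a,(b,c));`, tips associated a→A, b→B, c→C.

```python
from dtlscape import (CostBox, EventCosts, worked_instance, min_cost_fixed,
                      pareto_reconcile, partition_regions, consensus_support)

ri = worked_instance()
front = pareto_reconcile(ri, track_counts=True, track_events=True)
for entry in front.entries():
    d, t, l = entry.vector
    print(f"vector <{d},{t},{l}>  reconciliations: {entry.count}")

print("cost at (transfer=1, loss=1):", min_cost_fixed(ri, EventCosts(transfer=1, loss=1))[0])
print("cost at (transfer=5, loss=1):", min_cost_fixed(ri, EventCosts(transfer=5, loss=1))[0])

box = CostBox(transfer_min="0.1", transfer_max=5, loss_min="0.1", loss_max=5)
part = partition_regions(front, box)
for region in part.regions:
    d, t, l = region.vector
    print(f"region <{d},{t},{l}>  dim {region.dimension}  area {region.area} "
          f"(= {float(region.area):.4f})")
```

prints

```
vector <0,1,0>  reconciliations: 1
vector <1,0,3>  reconciliations: 1
cost at (transfer=1, loss=1): 1
cost at (transfer=5, loss=1): 4
region <0,1,0>  dim 2  area 13037/600 (= 21.7283)
region <1,0,3>  dim 2  area 1369/600 (= 2.2817)
```

Two Pareto vectors, hence two reconciliations worth reporting: one
speciation + one transfer (⟨0,1,0⟩, total cost 1 at unit costs) versus one
speciation + one duplication + three losses (⟨1,0,3⟩, total cost 4 when
transfers cost 5).  On the box [0.1, 5]² they split along the line
C<sub>Θ</sub> = 1 + 3·C<sub>L</sub>, with the transfer solution covering
13037/600 of the 2401/100 total area.  Consensus support makes the
trade-off explicit — the transfer event and the speciation under it are
common to every optimum in 90.5 % of the cost space:

```
transfer    b+c@B->C     regions: 1  area support: 0.905
speciation  a+b@A+B      regions: 1  area support: 0.905
duplication a+b@A+C      regions: 1  area support: 0.095
...
```

The same analyses run from the shell (`dtlscape costscape | eventscape |
sigscape | simulate`):

```sh
dtlscape costscape --host host.nwk --parasite parasite.nwk --mapping mapping.tsv \
    --tmin 0.1 --tmax 5 --lmin 0.1 --lmax 5 --out regions.json --plot regions.svg
dtlscape sigscape --host host.nwk --parasite parasite.nwk --mapping mapping.tsv \
    --permutations 1000 --grid 100 --seed 7 --out sig.json
```

Inputs are plain Newick plus a tab-separated tip mapping (or one combined
file with `HOSTTREE`/`PARASITETREE`/`MAPPING` sections); outputs are JSON or
CSV, with vertices and areas printed as exact rationals `p/q`.

## Documentation

`docs/methods.md` describes the model and its assumptions, the algebra of
front operations, the exact-geometry choices, what the simulator does and
does not emulate, and known limitations.
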