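"""Fixture generation: the minimal worked tanglegram and a cophylogeny
simulator with a known ground-truth scenario.

The simulator is deliberately simple — no dates, no rate heterogeneity.  Its
job is to produce valid, diverse reconciliation instances for which one valid
DTL-scenario (the generating history) is known, giving every property test a
parsimony upper bound and a replayable truth.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass

from .dtl_model import (
    DTLScenario,
    Event,
    EventCountVector,
    scenario_event_vector,
    scenario_events,
)
from .treeio import ReconInput, RootedBinaryTree, TreeNode, tree_from_nested

__all__ = [
    "SimParams",
    "SimResult",
    "SimulationError",
    "worked_instance",
    "simulate_cophylogeny",
    "write_fixtures",
]


def worked_instance() -> ReconInput:
    """The minimal 3-leaf tanglegram with the classic transfer-vs-duplication
    trade-off: species tree ((A,B),C), gene tree (a,(b,c)), a→A, b→B, c→C.

    Its Pareto front is {⟨0,1,0⟩, ⟨1,0,3⟩}: one speciation plus one transfer
    (total cost 1 when duplication = transfer = loss = 1), against one
    speciation, one duplication and three losses (total cost 4 when transfers
    cost 5).
    """
    species = tree_from_nested((("A", "B"), "C"))
    gene = tree_from_nested(("a", ("b", "c")))
    return ReconInput(
        species_tree=species,
        gene_tree=gene,
        mapping={"a": "A", "b": "B", "c": "C"},
    )


@dataclass(frozen=True)
class SimParams:
    """Simulator settings: species-tree size, per-arrival event probabilities
    (each in [0,1], summing to at most 1) and the seed."""

    n_species: int = 6
    p_dup: float = 0.1
    p_transfer: float = 0.1
    p_loss: float = 0.1
    seed: int = 0
    max_retries: int = 100
    max_gene_nodes: int = 500

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species leaves")
        for name in ("p_dup", "p_transfer", "p_loss"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_dup + self.p_transfer + self.p_loss > 1:
            raise ValueError("event probabilities must sum to at most 1")


@dataclass(frozen=True)
class SimResult:
    """A simulated instance with its generating history replayed as a valid
    DTL-scenario (the transfer recipients are the actual landing sites)."""

    recon_input: ReconInput
    true_scenario: DTLScenario
    true_events: frozenset[Event]
    true_vector: EventCountVector
    params: SimParams


class SimulationError(RuntimeError):
    pass


class _Rec:
    """Gene-lineage record node produced during simulation."""

    __slots__ = ("kind", "species", "children", "recipient")

    def __init__(self, kind: str, species: str, children=(), recipient: str | None = None):
        self.kind = kind  # speciation | duplication | transfer | leaf
        self.species = species
        self.children = tuple(children)
        self.recipient = recipient


def _random_species_tree(n: int, rng: random.Random) -> RootedBinaryTree:
    """Uniform random sequence of joins over labelled tips S1..Sn."""
    items: list = [f"S{i + 1}" for i in range(n)]
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2))
        joined = (items[i], items[j])
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(joined)
    return tree_from_nested(items[0])


def simulate_cophylogeny(params: SimParams) -> SimResult:
    """Evolve a gene lineage tip-ward through a random species tree.

    When a lineage arrives at a species node it either duplicates in place
    (two copies re-arrive at the same node), transfers (one copy stays, the
    other re-arrives at a uniformly chosen node incomparable to the current
    one), experiences a loss (at an internal node: the lineage follows only
    one child, so losses prune single branches and never kill whole
    subtrees), or — the default — co-diverges with the species (internal
    node) or becomes an extant gene (leaf).  Because every created gene node
    keeps both children, the recorded history replays directly into a valid
    DTL-scenario of the generated instance.

    Instances whose gene tree ends up with fewer than 2 leaves, or that
    exceed ``max_gene_nodes``, are rejected and resampled (bounded by
    ``max_retries``).
    """
    rng = random.Random(params.seed)
    for _ in range(params.max_retries):
        species = _random_species_tree(params.n_species, rng)
        counter = {"nodes": 0, "leaf": 0}

        def arrive(s: TreeNode) -> _Rec:
            counter["nodes"] += 1
            if counter["nodes"] > params.max_gene_nodes:
                raise SimulationError("gene tree exceeded the node budget")
            u = rng.random()
            if u < params.p_dup:
                return _Rec("duplication", s.label, (arrive(s), arrive(s)))
            if u < params.p_dup + params.p_transfer:
                targets = species.incomparable_nodes(s)
                if targets:
                    landing = rng.choice(targets)
                    # first child stays, second child jumps
                    return _Rec(
                        "transfer", s.label,
                        (arrive(s), arrive(landing)),
                        recipient=landing.label,
                    )
                # no incomparable node (species root): fall through to null event
            elif u < params.p_dup + params.p_transfer + params.p_loss and not s.is_leaf:
                survivor = rng.choice(s.children)
                return arrive(survivor)  # the other branch is a loss
            if s.is_leaf:
                counter["leaf"] += 1
                return _Rec("leaf", s.label)
            s1, s2 = s.children
            return _Rec("speciation", s.label, (arrive(s1), arrive(s2)))

        try:
            record = arrive(species.root)
        except SimulationError:
            continue
        if counter["leaf"] < 2:
            continue
        return _assemble(species, record, params)
    raise SimulationError(
        f"no usable instance after {params.max_retries} attempts; "
        "lower the event probabilities or raise the caps"
    )


def _assemble(species: RootedBinaryTree, record: _Rec, params: SimParams) -> SimResult:
    leaf_counter = [0]

    def nested(rec: _Rec):
        if rec.kind == "leaf":
            leaf_counter[0] += 1
            return f"{rec.species.lower()}_g{leaf_counter[0]}"
        return tuple(nested(c) for c in rec.children)

    shape = nested(record)
    gene = tree_from_nested(shape)

    mapping: dict[str, str] = {}
    M: dict[str, str] = {}
    sigma: set[str] = set()
    delta: set[str] = set()
    theta: set[str] = set()
    xi: set[tuple[str, str]] = set()
    tau: dict[str, str] = {}

    def walk(rec: _Rec, node: TreeNode) -> None:
        M[node.label] = rec.species
        if rec.kind == "leaf":
            mapping[node.label] = rec.species
            return
        if rec.kind == "speciation":
            sigma.add(node.label)
        elif rec.kind == "duplication":
            delta.add(node.label)
        else:
            theta.add(node.label)
            jump_child = node.children[1]
            xi.add((node.label, jump_child.label))
            tau[node.label] = rec.recipient  # the actual landing node
        for sub, child in zip(rec.children, node.children):
            walk(sub, child)

    walk(record, gene.root)
    ri = ReconInput(species_tree=species, gene_tree=gene, mapping=mapping)
    scenario = DTLScenario(
        mapping=M, sigma=frozenset(sigma), delta=frozenset(delta),
        theta=frozenset(theta), xi=frozenset(xi), tau=tau,
    )
    events = scenario_events(ri, scenario)
    vector = scenario_event_vector(ri, scenario)
    return SimResult(
        recon_input=ri,
        true_scenario=scenario,
        true_events=events,
        true_vector=vector,
        params=params,
    )


def write_fixtures(result: SimResult, directory) -> dict[str, str]:
    """Write host/parasite Newick files, the mapping TSV, and the true history
    as JSON into ``directory``; returns the file paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "host": os.path.join(directory, "host.nwk"),
        "parasite": os.path.join(directory, "parasite.nwk"),
        "mapping": os.path.join(directory, "mapping.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    ri = result.recon_input
    with open(paths["host"], "w") as fh:
        fh.write(ri.species_tree.newick() + "\n")
    with open(paths["parasite"], "w") as fh:
        fh.write(ri.gene_tree.newick() + "\n")
    with open(paths["mapping"], "w") as fh:
        for gene in ri.gene_tree.leaf_labels:
            fh.write(f"{gene}\t{ri.mapping[gene]}\n")
    truth = {
        "vector": list(result.true_vector),
        "mapping": result.true_scenario.mapping,
        "speciations": sorted(result.true_scenario.sigma),
        "duplications": sorted(result.true_scenario.delta),
        "transfers": sorted(result.true_scenario.theta),
        "transfer_edges": sorted(list(e) for e in result.true_scenario.xi),
        "recipients": result.true_scenario.tau,
        "seed": result.params.seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
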