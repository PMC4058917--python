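import random

import pytest

from dtlscape import (
    CostBox,
    DTLScenario,
    ReconInput,
    SimParams,
    worked_instance,
    simulate_cophylogeny,
    tree_from_nested,
)


@pytest.fixture
def worked() -> ReconInput:
    return worked_instance()


@pytest.fixture
def transfer_scenario() -> DTLScenario:
    """One speciation (at lca(A,B)) and one transfer (b stays at B, c jumps
    to C): event vector ⟨0,1,0⟩."""
    return DTLScenario(
        mapping={"a": "A", "b": "B", "c": "C", "b+c": "B", "a+b": "A+B"},
        sigma=frozenset({"a+b"}),
        delta=frozenset(),
        theta=frozenset({"b+c"}),
        xi=frozenset({("b+c", "c")}),
        tau={"b+c": "C"},
    )


@pytest.fixture
def duplication_scenario() -> DTLScenario:
    """One duplication at the species root and one speciation: ⟨1,0,3⟩."""
    return DTLScenario(
        mapping={"a": "A", "b": "B", "c": "C", "b+c": "A+C", "a+b": "A+C"},
        sigma=frozenset({"b+c"}),
        delta=frozenset({"a+b"}),
        theta=frozenset(),
    )


@pytest.fixture
def default_box() -> CostBox:
    return CostBox(transfer_min="0.1", transfer_max=5, loss_min="0.1", loss_max=5)


def congruent_instance(n_leaves: int = 4) -> ReconInput:
    """Perfectly congruent tanglegram: gene tree a copy of the species tree
    with the identity tip association."""
    sim = simulate_cophylogeny(
        SimParams(n_species=n_leaves, p_dup=0, p_transfer=0, p_loss=0, seed=1)
    )
    return sim.recon_input


def random_tiny_instances(count: int, max_leaves: int = 5, start_seed: int = 0):
    """Simulated instances with at most ``max_leaves`` leaves in each tree,
    suitable for the exhaustive-enumeration oracle."""
    instances = []
    seed = start_seed
    rng = random.Random(start_seed)
    while len(instances) < count:
        n_species = rng.randint(2, max_leaves)
        sim = simulate_cophylogeny(
            SimParams(
                n_species=n_species,
                p_dup=0.15,
                p_transfer=0.15,
                p_loss=0.15,
                seed=seed,
            )
        )
        seed += 1
        if len(sim.recon_input.gene_tree.leaves) <= max_leaves:
            instances.append(sim)
    return instances


def random_nested(labels, rng: random.Random):
    """Uniform random join order over the given leaf labels."""
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2))
        joined = (items[i], items[j])
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(joined)
    return items[0]


def random_instance(rng: random.Random, max_leaves: int = 5) -> ReconInput:
    """A random tanglegram with an arbitrary (not simulated) tip mapping."""
    ns, ng = rng.randint(2, max_leaves), rng.randint(2, max_leaves)
    species = tree_from_nested(random_nested([f"S{i}" for i in range(ns)], rng))
    gene = tree_from_nested(random_nested([f"g{i}" for i in range(ng)], rng))
    mapping = {g: rng.choice(species.leaf_labels) for g in gene.leaf_labels}
    return ReconInput(species_tree=species, gene_tree=gene, mapping=mapping)
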