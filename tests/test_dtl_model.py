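import random
from dataclasses import replace
from fractions import Fraction

import pytest

from dtlscape import (
    EventCosts,
    EventCountVector,
    InstanceTooLargeError,
    ReconInput,
    count_losses,
    enumerate_scenarios,
    min_cost_fixed,
    reconciliation_cost,
    scenario_event_vector,
    tree_from_nested,
    validate_scenario,
)
from dtlscape.dtl_model import lca, path_distance


class TestBasicQueries:
    def test_lca(self, worked):
        S = worked.species_tree
        assert lca(S, ["A", "B"]).label == "A+B"
        assert lca(S, ["A", "C"]) is S.root
        assert lca(S, ["B"]).label == "B"

    def test_path_distance(self, worked):
        S = worked.species_tree
        assert path_distance(S, S.root, "A") == 2
        assert path_distance(S, "A", "A") == 0
        assert path_distance(S, "A", "C") == 3

    def test_unknown_node(self, worked):
        with pytest.raises(KeyError):
            path_distance(worked.species_tree, "A", "nope")


class TestScenarioValidity:
    def test_transfer_scenario_valid(self, worked, transfer_scenario):
        report = validate_scenario(worked, transfer_scenario)
        assert report.ok and not report.violations

    def test_duplication_scenario_valid(self, worked, duplication_scenario):
        assert validate_scenario(worked, duplication_scenario).ok

    def test_leaf_mapping_violation(self, worked, transfer_scenario):
        bad = replace(
            transfer_scenario,
            mapping={**transfer_scenario.mapping, "a": "B"},
        )
        report = validate_scenario(worked, bad)
        assert not report.ok and "1" in report.violations

    def test_speciation_with_comparable_images_violation(self, worked, duplication_scenario):
        # relabel the duplication node (children map to A and the root) as a
        # speciation: its children's images are comparable, breaking 4a
        bad = replace(
            duplication_scenario,
            sigma=frozenset({"a+b", "b+c"}),
            delta=frozenset(),
        )
        report = validate_scenario(worked, bad)
        assert not report.ok and "4a" in report.violations

    def test_transfer_edge_mismatch_violation(self, worked, transfer_scenario):
        bad = replace(transfer_scenario, xi=frozenset())
        report = validate_scenario(worked, bad)
        assert not report.ok and "3" in report.violations

    def test_dangling_reference_is_structural(self, worked, transfer_scenario):
        bad = replace(
            transfer_scenario,
            mapping={**transfer_scenario.mapping, "a+b": "nowhere"},
        )
        with pytest.raises(ValueError, match="unknown species node"):
            validate_scenario(worked, bad)


class TestLossesAndVectors:
    def test_transfer_scenario_has_no_losses(self, worked, transfer_scenario):
        total, events = count_losses(worked, transfer_scenario)
        assert total == 0 and events == []
        assert scenario_event_vector(worked, transfer_scenario) == (0, 1, 0)

    def test_duplication_scenario_has_three_losses(self, worked, duplication_scenario):
        total, events = count_losses(worked, duplication_scenario)
        assert total == 3
        assert len(events) == total
        assert scenario_event_vector(worked, duplication_scenario) == (1, 0, 3)

    def test_congruent_two_leaf_instance(self):
        species = tree_from_nested(("A", "B"))
        gene = tree_from_nested(("x", "y"))
        ri = ReconInput(species_tree=species, gene_tree=gene, mapping={"x": "A", "y": "B"})
        scenarios = enumerate_scenarios(ri)
        vectors = {tuple(v) for _, v in scenarios}
        assert (0, 0, 0) in vectors
        assert min_cost_fixed(ri, EventCosts(transfer=1, loss=1))[0] == 0

    def test_loss_event_count_matches_total(self, worked):
        for scenario, vector in enumerate_scenarios(worked):
            total, events = count_losses(worked, scenario)
            assert total == len(events) == vector.losses


class TestReconciliationCost:
    @pytest.mark.parametrize(
        "vector,costs,expected",
        [
            ((0, 1, 0), (1, 1, 1), 1),
            ((1, 0, 3), (1, 5, 1), 4),
            ((0, 0, 0), (1, 7, 3), 0),
            ((2, 1, 4), (1, Fraction(3, 2), Fraction(1, 2)), Fraction(11, 2)),
        ],
    )
    def test_cost_formula(self, vector, costs, expected):
        dup, transfer, loss = costs
        c = EventCosts(duplication=dup, transfer=transfer, loss=loss)
        assert reconciliation_cost(EventCountVector(*vector), c) == expected

    def test_nonpositive_costs_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            EventCosts(transfer=0, loss=1)
        with pytest.raises(ValueError, match="strictly positive"):
            EventCosts(transfer=1, loss=-2)


class TestEnumerationOracle:
    def test_single_leaf_trees(self):
        ri = ReconInput(
            species_tree=tree_from_nested("A"),
            gene_tree=tree_from_nested("a"),
            mapping={"a": "A"},
        )
        scenarios = enumerate_scenarios(ri)
        assert len(scenarios) == 1
        assert tuple(scenarios[0][1]) == (0, 0, 0)

    def test_worked_instance_scenarios_include_tradeoff_vectors(self, worked):
        vectors = {tuple(v) for _, v in enumerate_scenarios(worked)}
        assert {(0, 1, 0), (0, 1, 1), (1, 0, 3), (0, 2, 0)} <= vectors

    def test_every_scenario_is_valid(self, worked):
        for scenario, _ in enumerate_scenarios(worked):
            assert validate_scenario(worked, scenario).ok

    def test_size_cap(self):
        rng = random.Random(0)
        labels = [f"S{i}" for i in range(8)]
        from conftest import random_nested

        species = tree_from_nested(random_nested(labels, rng))
        gene = tree_from_nested(random_nested([f"g{i}" for i in range(8)], rng))
        ri = ReconInput(
            species_tree=species,
            gene_tree=gene,
            mapping={g: rng.choice(labels) for g in gene.leaf_labels},
        )
        with pytest.raises(InstanceTooLargeError):
            enumerate_scenarios(ri)


class TestFixedCostOptimum:
    def test_worked_instance_costs(self, worked):
        assert min_cost_fixed(worked, EventCosts(transfer=1, loss=1))[0] == 1
        assert min_cost_fixed(worked, EventCosts(transfer=5, loss=1))[0] == 4

    def test_methods_agree_with_counts(self, worked):
        rng = random.Random(7)
        for _ in range(20):
            costs = EventCosts(
                transfer=Fraction(rng.randint(1, 40), rng.randint(1, 8)),
                loss=Fraction(rng.randint(1, 40), rng.randint(1, 8)),
            )
            assert min_cost_fixed(worked, costs, "front") == min_cost_fixed(
                worked, costs, "enumerate"
            )
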