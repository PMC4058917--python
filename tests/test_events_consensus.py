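from fractions import Fraction

import pytest

from dtlscape import (
    consensus_support,
    enumerate_scenarios,
    pareto_reconcile,
    partition_by_region_count,
    partition_regions,
    region_event_table,
    scenario_events,
)
from conftest import congruent_instance, random_tiny_instances


def worked_partition(worked, box):
    front = pareto_reconcile(worked, track_counts=True, track_events=True)
    return partition_regions(front, box)


class TestRegionEventTable:
    def test_worked_instance_transfer_region(self, worked, default_box):
        table = region_event_table(worked_partition(worked, default_box).regions)
        transfer_region = table[(0, 1, 0)]
        kinds = {(e.kind, e.gene, e.species, e.recipient) for e in transfer_region}
        assert ("transfer", "b+c", "B", "C") in kinds
        assert ("speciation", "a+b", "A+B", None) in kinds

    def test_congruent_instance_all_speciations(self, default_box):
        ri = congruent_instance(5)
        part = partition_regions(
            pareto_reconcile(ri, track_counts=True, track_events=True), default_box
        )
        assert len(part.regions) == 1
        events = part.regions[0].common_events
        assert {e.kind for e in events} == {"speciation"}
        assert len(events) == len(ri.gene_tree.internal_nodes)

    def test_multicount_region_matches_enumeration(self, default_box):
        # find a simulated instance whose front has a vector achieved by
        # several reconciliations and verify the intersection directly
        checked = 0
        for sim in random_tiny_instances(12, start_seed=700):
            ri = sim.recon_input
            part = partition_regions(
                pareto_reconcile(ri, track_counts=True, track_events=True), default_box
            )
            multi = [r for r in part.regions if r.count and r.count >= 2]
            if not multi:
                continue
            scenarios = enumerate_scenarios(ri)
            for region in multi:
                sets = [
                    scenario_events(ri, sc)
                    for sc, v in scenarios
                    if tuple(v) == tuple(region.vector)
                ]
                assert len(sets) == region.count
                assert frozenset.intersection(*sets) == region.common_events
                checked += 1
        assert checked >= 1

    def test_missing_annotations_rejected(self, worked, default_box):
        part = partition_regions(pareto_reconcile(worked, track_counts=True), default_box)
        with pytest.raises(ValueError, match="track_events"):
            region_event_table(part.regions)


class TestRegionCountPartition:
    def test_single_region_bucket(self, default_box):
        ri = congruent_instance(4)
        part = partition_regions(
            pareto_reconcile(ri, track_counts=True, track_events=True), default_box
        )
        buckets = partition_by_region_count(part.regions)
        assert set(buckets) == {1}
        assert buckets[1] == set(part.regions[0].common_events)

    def test_worked_instance_buckets_all_singleton(self, worked, default_box):
        # the root speciation maps to different species nodes in the two
        # regions, so no event is shared between them
        part = worked_partition(worked, default_box)
        buckets = partition_by_region_count(part.regions)
        assert set(buckets) == {1}
        union = set().union(*(r.common_events for r in part.regions))
        assert buckets[1] == union

    def test_buckets_partition_the_union(self, default_box):
        for sim in random_tiny_instances(5, start_seed=900):
            part = partition_regions(
                pareto_reconcile(sim.recon_input, track_counts=True, track_events=True),
                default_box,
            )
            buckets = partition_by_region_count(part.regions)
            union = set().union(*(r.common_events for r in part.regions))
            collected = set()
            for k, events in buckets.items():
                assert 1 <= k <= len(part.regions)
                assert collected.isdisjoint(events)
                collected |= events
            assert collected == union


class TestConsensusSupport:
    def test_event_common_everywhere_has_full_support(self, default_box):
        ri = congruent_instance(5)
        part = partition_regions(
            pareto_reconcile(ri, track_counts=True, track_events=True), default_box
        )
        table = consensus_support(part.regions, default_box)
        for row in table.rows:
            assert row.region_fraction == 1
            assert row.area_fraction == 1

    def test_region_fraction_arithmetic(self, worked, default_box):
        part = worked_partition(worked, default_box)
        table = consensus_support(part.regions, default_box)
        assert all(row.region_fraction == Fraction(1, 2) for row in table.rows)

    def test_area_fraction_of_transfer_event(self, worked, default_box):
        part = worked_partition(worked, default_box)
        transfer_area = next(
            r.area for r in part.regions if tuple(r.vector) == (0, 1, 0)
        )
        table = consensus_support(part.regions, default_box)
        transfer_rows = [r for r in table.rows if r.event.kind == "transfer"]
        assert len(transfer_rows) == 1
        assert transfer_rows[0].area_fraction == transfer_area / default_box.area

    def test_single_region_support_is_zero_or_one(self, default_box):
        ri = congruent_instance(4)
        part = partition_regions(
            pareto_reconcile(ri, track_counts=True, track_events=True), default_box
        )
        table = consensus_support(part.regions, default_box)
        for row in table.rows:
            assert row.region_fraction in (0, 1)

    def test_support_threshold_monotonicity(self, default_box):
        for sim in random_tiny_instances(5, start_seed=1100):
            part = partition_regions(
                pareto_reconcile(sim.recon_input, track_counts=True, track_events=True),
                default_box,
            )
            table = consensus_support(part.regions, default_box)
            for measure in ("region_fraction", "area_fraction"):
                previous = None
                for s in (Fraction(k, 10) for k in range(11)):
                    current = table.events_with_support(s, measure)
                    if previous is not None:
                        assert current <= previous
                    previous = current
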