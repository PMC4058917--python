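import random
from collections import Counter, defaultdict

import pytest
from hypothesis import given, settings, strategies as st

from dtlscape import (
    AnnotatedFront,
    AnnotatedVector,
    EventCountVector,
    ReconInput,
    enumerate_scenarios,
    pareto_combine,
    pareto_filter,
    pareto_merge,
    pareto_reconcile,
    scenario_events,
    tree_from_nested,
)
from conftest import congruent_instance, random_instance, random_tiny_instances


def make_front(entries):
    return AnnotatedFront(
        AnnotatedVector(EventCountVector(*v), count, frozenset(events))
        for v, count, events in entries
    )


def naive_combine(a: AnnotatedFront, b: AnnotatedFront) -> AnnotatedFront:
    """Cartesian-product-then-filter reference for the ⊗ operation."""
    sums = defaultdict(lambda: [0, None])
    for ea in a.entries():
        for eb in b.entries():
            v = ea.vector + eb.vector
            acc = sums[v]
            acc[0] += ea.count * eb.count
            pair_events = ea.events | eb.events
            acc[1] = pair_events if acc[1] is None else acc[1] & pair_events
    keep = pareto_filter(sums.keys())
    return AnnotatedFront(
        AnnotatedVector(v, c, e) for v, (c, e) in sums.items() if v in keep
    )


class TestParetoFilter:
    def test_dominated_removed(self):
        assert pareto_filter([(1, 1, 1), (1, 1, 2)]) == {EventCountVector(1, 1, 1)}

    def test_incomparable_kept(self):
        vs = [(0, 1, 0), (1, 0, 3)]
        assert pareto_filter(vs) == {EventCountVector(*v) for v in vs}

    def test_empty(self):
        assert pareto_filter([]) == set()

    def test_filter_is_maximal_antichain(self):
        rng = random.Random(3)
        vectors = [
            EventCountVector(rng.randint(0, 4), rng.randint(0, 4), rng.randint(0, 6))
            for _ in range(60)
        ]
        front = pareto_filter(vectors)
        for kept in front:
            assert not any(o.dominates(kept) for o in front)
        for v in vectors:
            assert any(f == v or f.dominates(v) for f in front)


class TestMerge:
    def test_union_of_incomparable(self):
        a = make_front([((0, 1, 0), 1, [])])
        b = make_front([((1, 0, 3), 1, [])])
        merged = pareto_merge(a, b)
        assert merged.vectors() == {(0, 1, 0), (1, 0, 3)}

    def test_counts_add_for_equal_vectors(self):
        a = make_front([((1, 1, 1), 2, ["x", "y"])])
        b = make_front([((1, 1, 1), 3, ["y", "z"])])
        merged = pareto_merge(a, b)
        entry = merged.get((1, 1, 1))
        assert entry.count == 5
        assert entry.events == {"y"}

    def test_empty_is_identity(self):
        a = make_front([((0, 1, 0), 1, []), ((1, 0, 2), 4, [])])
        assert pareto_merge(a, AnnotatedFront.empty()) == a
        assert pareto_merge(AnnotatedFront.empty(), a) == a


class TestCombine:
    def test_singleton_sum(self):
        a = make_front([((0, 1, 0), 1, [])])
        b = make_front([((1, 0, 3), 1, [])])
        assert pareto_combine(a, b).vectors() == {(1, 1, 3)}

    def test_two_by_two(self):
        f = make_front([((0, 0, 1), 1, []), ((0, 1, 0), 1, [])])
        assert pareto_combine(f, f).vectors() == {(0, 0, 2), (0, 1, 1), (0, 2, 0)}

    def test_empty_absorbs(self):
        a = make_front([((0, 1, 0), 1, [])])
        assert pareto_combine(a, AnnotatedFront.empty()) == AnnotatedFront.empty()

    def test_counts_multiply_and_add(self):
        a = make_front([((1, 0, 0), 2, ["p"]), ((0, 1, 0), 3, ["q"])])
        b = make_front([((0, 1, 0), 5, ["r"]), ((1, 0, 0), 7, ["s"])])
        combined = pareto_combine(a, b)
        # (1,1,0) arises as (1,0,0)+(0,1,0) [2*5] and (0,1,0)+(1,0,0) [3*7]
        assert combined.get((1, 1, 0)).count == 2 * 5 + 3 * 7
        assert combined.get((1, 1, 0)).events == frozenset()  # {p,r} ∩ {q,s}

    annotated_fronts = st.builds(
        lambda entries: make_front(
            (v, c, [f"e{i}" for i in ids]) for v, c, ids in entries
        ),
        st.lists(
            st.tuples(
                st.tuples(
                    st.integers(0, 5), st.integers(0, 5), st.integers(0, 8)
                ),
                st.integers(1, 4),
                st.sets(st.integers(0, 6), max_size=3),
            ),
            min_size=0,
            max_size=12,
        ),
    )

    @settings(max_examples=120, derandomize=True)
    @given(a=annotated_fronts, b=annotated_fronts)
    def test_combine_matches_naive_oracle(self, a, b):
        assert pareto_combine(a, b) == naive_combine(a, b)


class TestParetoReconcile:
    def test_worked_instance_front(self, worked):
        front = pareto_reconcile(worked, track_counts=True)
        assert front.vectors() == {(0, 1, 0), (1, 0, 3)}
        assert all(entry.count == 1 for entry in front.entries())

    def test_congruent_tanglegram(self):
        ri = congruent_instance(5)
        front = pareto_reconcile(ri, track_counts=True)
        assert front.vectors() == {(0, 0, 0)}
        assert front.get((0, 0, 0)).count == 1

    def test_single_leaf_gene_tree(self):
        species = tree_from_nested((("A", "B"), "C"))
        gene = tree_from_nested("g")
        ri = ReconInput(species_tree=species, gene_tree=gene, mapping={"g": "B"})
        assert pareto_reconcile(ri).vectors() == {(0, 0, 0)}

    def test_tracking_flags_do_not_change_vectors(self):
        rng = random.Random(11)
        for _ in range(5):
            ri = random_instance(rng)
            bare = pareto_reconcile(ri, track_counts=False, track_events=False)
            counted = pareto_reconcile(ri, track_counts=True, track_events=False)
            full = pareto_reconcile(ri, track_counts=True, track_events=True)
            assert bare.vectors() == counted.vectors() == full.vectors()
            # the two out-table code paths must also agree on counts
            assert [(e.vector, e.count) for e in counted.entries()] == [
                (e.vector, e.count) for e in full.entries()
            ]

    def test_matches_enumeration_on_random_mappings(self):
        rng = random.Random(23)
        for _ in range(10):
            ri = random_instance(rng, max_leaves=4)
            front = pareto_reconcile(ri, track_counts=True, track_events=True)
            scenarios = enumerate_scenarios(ri)
            assert front.vectors() == pareto_filter(v for _, v in scenarios)
            counts = Counter(tuple(v) for _, v in scenarios)
            for entry in front.entries():
                assert entry.count == counts[tuple(entry.vector)]

    def test_front_is_antichain_with_unique_columns(self):
        for sim in random_tiny_instances(8, start_seed=100):
            ri = sim.recon_input
            front = pareto_reconcile(ri)
            vectors = front.vectors()
            for v in vectors:
                assert not any(o.dominates(v) for o in vectors)
            columns = [(v.duplications, v.transfers) for v in vectors]
            assert len(columns) == len(set(columns))
            internal = len(ri.gene_tree.internal_nodes)
            assert all(v.duplications + v.transfers <= internal for v in vectors)

    def test_common_events_match_oracle(self):
        for sim in random_tiny_instances(6, start_seed=500):
            ri = sim.recon_input
            front = pareto_reconcile(ri, track_counts=True, track_events=True)
            by_vector = defaultdict(list)
            for scenario, vector in enumerate_scenarios(ri):
                by_vector[tuple(vector)].append(scenario_events(ri, scenario))
            for entry in front.entries():
                expected = frozenset.intersection(*by_vector[tuple(entry.vector)])
                assert entry.events == expected
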