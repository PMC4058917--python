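"""Pareto-front dynamic programming over reconciliation event counts.

The centrepiece is :func:`pareto_reconcile`, a nested post-order dynamic
program over the gene tree T and species tree S that computes, for every pair
(t, s), the antichain of Pareto-optimal event count vectors for reconciling
T(t) with S such that t maps to s.  Sub-fronts are combined with two
operations:

* ``pareto_merge`` (⊕) — union of two fronts followed by Pareto filtering;
  the identity is the empty front (infeasibility).
* ``pareto_combine`` (⊗) — vector sums over the Cartesian product, filtered;
  the empty front is absorbing.

Each front entry optionally carries the number of distinct reconciliations
achieving its vector and the set of events common to all of them.  Counts add
across alternative derivations of the same vector and multiply across
composition; common-event sets intersect across alternatives and union across
composition.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass
from typing import Iterable, Iterator

from .dtl_model import Event, EventCountVector
from .treeio import ReconInput, TreeNode

__all__ = [
    "AnnotatedVector",
    "AnnotatedFront",
    "pareto_filter",
    "pareto_merge",
    "pareto_combine",
    "pareto_reconcile",
]


@dataclass(frozen=True)
class AnnotatedVector:
    """A Pareto-front entry: the event count vector, the number of distinct
    reconciliations achieving it (None if not tracked) and the events common
    to every one of them (None if not tracked)."""

    vector: EventCountVector
    count: int | None = None
    events: frozenset[Event] | None = None


def _merge_alternative(a: AnnotatedVector, b: AnnotatedVector) -> AnnotatedVector:
    """Same vector reached two different ways: counts add, commons intersect."""
    count = None if a.count is None or b.count is None else a.count + b.count
    events = None if a.events is None or b.events is None else a.events & b.events
    return AnnotatedVector(a.vector, count, events)


def _compose_pair(a: AnnotatedVector, b: AnnotatedVector) -> AnnotatedVector:
    """Independent subsolutions joined: counts multiply, events union."""
    count = None if a.count is None or b.count is None else a.count * b.count
    events = None if a.events is None or b.events is None else a.events | b.events
    return AnnotatedVector(a.vector + b.vector, count, events)


class AnnotatedFront:
    """An antichain of event count vectors with optional annotations.

    No member strictly dominates another and no two members share a
    (duplication, transfer) pair.  The empty front denotes infeasibility.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Iterable[AnnotatedVector] = ()):
        by_vector: dict[EventCountVector, AnnotatedVector] = {}
        for e in entries:
            v = EventCountVector(*e.vector)
            e = AnnotatedVector(v, e.count, e.events)
            by_vector[v] = _merge_alternative(by_vector[v], e) if v in by_vector else e
        kept = _filter_dominated(list(by_vector.values()))
        self._entries = {e.vector: e for e in kept}

    @classmethod
    def _trusted(cls, entries: list[AnnotatedVector]) -> "AnnotatedFront":
        front = cls.__new__(cls)
        front._entries = {e.vector: e for e in entries}
        return front

    @classmethod
    def empty(cls) -> "AnnotatedFront":
        return cls._trusted([])

    @classmethod
    def singleton(
        cls,
        vector: EventCountVector = EventCountVector(0, 0, 0),
        count: int | None = 1,
        events: frozenset[Event] | None = frozenset(),
    ) -> "AnnotatedFront":
        return cls._trusted([AnnotatedVector(EventCountVector(*vector), count, events)])

    def vectors(self) -> set[EventCountVector]:
        return set(self._entries)

    def entries(self) -> list[AnnotatedVector]:
        return sorted(self._entries.values(), key=lambda e: e.vector)

    def get(self, vector) -> AnnotatedVector:
        return self._entries[EventCountVector(*vector)]

    def shifted(
        self, dd: int = 0, dt: int = 0, dl: int = 0, add_events: frozenset[Event] = frozenset()
    ) -> "AnnotatedFront":
        """The front with every vector incremented by (dd, dt, dl) and, when
        tracking, ``add_events`` attached to every entry.  Increments preserve
        the antichain property."""
        out = []
        for e in self._entries.values():
            vector = EventCountVector(e.vector[0] + dd, e.vector[1] + dt, e.vector[2] + dl)
            events = e.events if e.events is None else e.events | add_events
            out.append(AnnotatedVector(vector, e.count, events))
        return AnnotatedFront._trusted(out)

    def __iter__(self) -> Iterator[AnnotatedVector]:
        return iter(self.entries())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, vector) -> bool:
        return EventCountVector(*vector) in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedFront):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        inner = ", ".join(str(tuple(e.vector)) for e in self.entries())
        return f"AnnotatedFront({{{inner}}})"


def _filter_dominated(entries: list[AnnotatedVector]) -> list[AnnotatedVector]:
    """Keep the maximal antichain; dominated entries are dropped outright
    (their reconciliations are not Pareto-optimal, so their annotations do not
    contribute)."""
    kept = []
    for e in entries:
        if not any(o.vector.dominates(e.vector) for o in entries if o is not e):
            kept.append(e)
    return kept


def pareto_filter(vectors: Iterable[EventCountVector]) -> set[EventCountVector]:
    """The Pareto-optimal subset of a multiset of event count vectors."""
    uniq = {EventCountVector(*v) for v in vectors}
    return {v for v in uniq if not any(o.dominates(v) for o in uniq)}


def pareto_merge(a: AnnotatedFront, b: AnnotatedFront) -> AnnotatedFront:
    """The ⊕ operation: Pareto filter of the union of two antichains."""
    if not a._entries:
        return b
    if not b._entries:
        return a
    merged: dict[EventCountVector, AnnotatedVector] = dict(a._entries)
    for v, e in b._entries.items():
        merged[v] = _merge_alternative(merged[v], e) if v in merged else e
    return AnnotatedFront._trusted(_filter_dominated(list(merged.values())))


def pareto_combine(a: AnnotatedFront, b: AnnotatedFront) -> AnnotatedFront:
    """The ⊗ operation: Pareto filter of all pairwise vector sums.

    Implemented with the lexicographically sorted working list: each sum is
    inserted in (δ, θ, ℓ) order and immediately resolved against its column
    neighbours — equal vectors merge their annotations, a sum with a cheaper
    entry already present in its (δ, θ) column is discarded, and a costlier
    column entry is evicted — so the list never holds more than one vector per
    (δ, θ).  A final cross-column sweep removes the remaining dominated
    vectors.
    """
    if not a._entries or not b._entries:
        return AnnotatedFront.empty()
    keys: list[EventCountVector] = []
    work: list[AnnotatedVector] = []
    for ea in a._entries.values():
        for eb in b._entries.values():
            c = _compose_pair(ea, eb)
            pos = bisect_left(keys, c.vector)
            if pos < len(keys) and keys[pos] == c.vector:
                work[pos] = _merge_alternative(work[pos], c)
                continue
            if pos > 0 and keys[pos - 1][:2] == c.vector[:2]:
                continue  # strictly dominated within its (δ, θ) column
            if pos < len(keys) and keys[pos][:2] == c.vector[:2]:
                del keys[pos], work[pos]  # evict the dominated column entry
            keys.insert(pos, c.vector)
            work.insert(pos, c)
    return AnnotatedFront._trusted(_filter_dominated(work))


# ---------------------------------------------------------------------------
# the reconciliation DP


class _Tables:
    """DP state: P, PΣ, PΔ, PΘ, in, inAlt, out, each indexed by
    (gene node, species node); a missing cell is the empty front."""

    def __init__(self):
        self.P: dict[tuple[str, str], AnnotatedFront] = {}
        self.in_: dict[tuple[str, str], AnnotatedFront] = {}
        self.in_alt: dict[tuple[str, str], AnnotatedFront] = {}
        self.out: dict[tuple[str, str], AnnotatedFront] = {}

    @staticmethod
    def cell(table: dict, t: TreeNode, s: TreeNode) -> AnnotatedFront:
        return table.get((t.label, s.label), _EMPTY)


_EMPTY = AnnotatedFront.empty()


def pareto_reconcile(
    ri: ReconInput,
    track_counts: bool = True,
    track_events: bool = False,
) -> AnnotatedFront:
    """All Pareto-optimal event count vectors for a reconciliation instance.

    With ``track_counts`` each returned entry carries the number of distinct
    scenarios achieving its vector; with ``track_events`` it also carries the
    set of events present in every such scenario.  Tracking never changes the
    vector set.

    Transfer recipients follow the canonical zero-distance convention: the
    recipient of a transfer is the species node its transferred child maps to.
    Transfers into the species root are impossible (no node is incomparable to
    the root).
    """
    S, T = ri.species_tree, ri.gene_tree
    tb = _Tables()
    count0 = 1 if track_counts else None
    events0: frozenset[Event] | None = frozenset() if track_events else None

    def unit() -> AnnotatedFront:
        return AnnotatedFront.singleton(EventCountVector(0, 0, 0), count0, events0)

    def fill_in_tables(t: TreeNode) -> None:
        # in(t,s) = P(t,s) ⊕ (in(t,s')+one loss) ⊕ (in(t,s'')+one loss)
        # inAlt(t,s) = P(t,s) ⊕ inAlt(t,s') ⊕ inAlt(t,s'')
        for s in S.postorder:
            p = tb.cell(tb.P, t, s)
            if s.is_leaf:
                in_here, alt_here = p, p
            else:
                s1, s2 = s.children
                in_here, alt_here = p, p
                for down, lost in ((s1, s2), (s2, s1)):
                    sub = tb.cell(tb.in_, t, down)
                    if len(sub):
                        loss = (
                            frozenset([Event(kind="loss", gene=t.label,
                                             species=s.label, species_child=lost.label)])
                            if track_events else frozenset()
                        )
                        in_here = pareto_merge(in_here, sub.shifted(dl=1, add_events=loss))
                    alt_here = pareto_merge(alt_here, tb.cell(tb.in_alt, t, down))
            if len(in_here):
                tb.in_[(t.label, s.label)] = in_here
            if len(alt_here):
                tb.in_alt[(t.label, s.label)] = alt_here

    def fill_out_tables(t: TreeNode) -> None:
        # out(t,s) = ⊕ over x incomparable to s of P(t,x); out(t, rt(S)) = ∅.
        # The pre-order recurrence is O(1) amortized per cell; the direct form
        # is used when tracking events so that the recipient-specific transfer
        # event (at t's parent) can be attached as each P(t,x) flows in.
        if t.parent is None:
            return  # out(rt(T), ·) is never consumed
        if track_events:
            parent = t.parent.label
            for s in S.postorder:
                acc = _EMPTY
                for x in S.incomparable_nodes(s):
                    p = tb.cell(tb.P, t, x)
                    if len(p):
                        ev = frozenset([Event(kind="transfer", gene=parent, species=s.label,
                                              recipient=x.label, gene_child=t.label)])
                        acc = pareto_merge(acc, p.shifted(add_events=ev))
                if len(acc):
                    tb.out[(t.label, s.label)] = acc
        else:
            for s in _preorder(S):
                if s.is_leaf:
                    continue
                s1, s2 = s.children
                here = tb.cell(tb.out, t, s)
                for child, other in ((s1, s2), (s2, s1)):
                    val = pareto_merge(here, tb.cell(tb.in_alt, t, other))
                    if len(val):
                        tb.out[(t.label, child.label)] = val

    # leaf initialization
    for t in T.leaves:
        target = S.node(ri.mapping[t.label])
        tb.P[(t.label, target.label)] = unit()
        fill_in_tables(t)
        fill_out_tables(t)

    for t in T.internal_nodes:  # gene-tree post-order
        t1, t2 = t.children
        for s in S.postorder:
            dup_event = (
                frozenset([Event(kind="duplication", gene=t.label, species=s.label)])
                if track_events else frozenset()
            )
            if s.is_leaf:
                p_sigma = _EMPTY  # speciation needs incomparable child images
                p_delta = pareto_combine(
                    tb.cell(tb.P, t1, s), tb.cell(tb.P, t2, s)
                ).shifted(dd=1, add_events=dup_event)
            else:
                s1, s2 = s.children
                p_sigma = pareto_merge(
                    pareto_combine(tb.cell(tb.in_, t1, s1), tb.cell(tb.in_, t2, s2)),
                    pareto_combine(tb.cell(tb.in_, t2, s1), tb.cell(tb.in_, t1, s2)),
                )
                if len(p_sigma) and track_events:
                    spec = frozenset([Event(kind="speciation", gene=t.label, species=s.label)])
                    p_sigma = p_sigma.shifted(add_events=spec)
                p_delta = pareto_combine(
                    tb.cell(tb.in_, t1, s), tb.cell(tb.in_, t2, s)
                ).shifted(dd=1, add_events=dup_event)
            if s.parent is None:
                p_theta = _EMPTY  # no transfers at the species root
            else:
                p_theta = pareto_merge(
                    pareto_combine(tb.cell(tb.in_, t1, s), tb.cell(tb.out, t2, s)),
                    pareto_combine(tb.cell(tb.in_, t2, s), tb.cell(tb.out, t1, s)),
                ).shifted(dt=1)
            p = pareto_merge(pareto_merge(p_sigma, p_delta), p_theta)
            if len(p):
                tb.P[(t.label, s.label)] = p
        fill_in_tables(t)
        fill_out_tables(t)

    result = _EMPTY
    for s in S.postorder:
        result = pareto_merge(result, tb.cell(tb.P, T.root, s))
    return result


def _preorder(S) -> list[TreeNode]:
    return sorted(S.postorder, key=lambda n: n._tin)
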