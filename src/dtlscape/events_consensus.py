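"""Consensus of events across cost-space regions.

For each region, the events common to *every* maximum-parsimony
reconciliation in that region are exactly the common events of its Pareto
vector (at an interior point of a region the optimal reconciliations are
those achieving the region's vector).  These per-region sets are partitioned
by how many regions share each event, and summarized as consensus support:
an event has support s when it is common to all reconciliations in at least
a fraction s of the regions (region measure) or of the box area covered by
its regions (area measure).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .costspace import CostBox, Region
from .dtl_model import Event, EventCountVector

__all__ = [
    "SupportRow",
    "SupportTable",
    "region_event_table",
    "partition_by_region_count",
    "consensus_support",
]


@dataclass(frozen=True)
class SupportRow:
    event: Event
    region_count: int
    region_fraction: Fraction
    area_fraction: Fraction


@dataclass(frozen=True)
class SupportTable:
    """Per-event consensus support under both measures."""

    rows: tuple[SupportRow, ...]
    n_regions: int
    box_area: Fraction

    def support(self, event: Event, measure: str = "region_fraction") -> Fraction:
        for row in self.rows:
            if row.event == event:
                return getattr(row, _check_measure(measure))
        return Fraction(0)

    def events_with_support(self, s, measure: str = "region_fraction") -> set[Event]:
        """Events common to every reconciliation in at least a fraction ``s``
        (inclusive) of the regions / of the area."""
        attr = _check_measure(measure)
        threshold = Fraction(str(s)) if isinstance(s, float) else Fraction(s)
        return {row.event for row in self.rows if getattr(row, attr) >= threshold}


def _check_measure(measure: str) -> str:
    if measure not in ("region_fraction", "area_fraction"):
        raise ValueError(f"unknown measure {measure!r}")
    return measure


def _require_annotations(regions: Sequence[Region]) -> None:
    missing = [r.vector for r in regions if r.common_events is None]
    if missing:
        raise ValueError(
            "regions lack common-event annotations (run pareto_reconcile with "
            f"track_events=True): {[tuple(v) for v in missing]}"
        )


def region_event_table(regions: Iterable[Region]) -> dict[EventCountVector, frozenset[Event]]:
    """Each region's common-event set, keyed by its (unique) Pareto vector."""
    regions = list(regions)
    _require_annotations(regions)
    return {r.vector: r.common_events for r in regions}  # type: ignore[misc]


def partition_by_region_count(regions: Iterable[Region]) -> dict[int, set[Event]]:
    """Partition the union of the regions' common events into buckets: the
    events common in exactly k regions, for k = 1..K.  Buckets are disjoint
    and only non-empty buckets are returned."""
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one region")
    _require_annotations(regions)
    tally: dict[Event, int] = {}
    for region in regions:
        for event in region.common_events:  # type: ignore[union-attr]
            tally[event] = tally.get(event, 0) + 1
    buckets: dict[int, set[Event]] = {}
    for event, k in tally.items():
        buckets.setdefault(k, set()).add(event)
    return buckets


def consensus_support(
    regions: Iterable[Region],
    box: CostBox,
    measure: str = "region_fraction",
) -> SupportTable:
    """Consensus support of every event that is common somewhere.

    region_fraction: number of regions where the event is common to all
    reconciliations, over the total number of regions (zero-area regions
    count fully).  area_fraction: summed area of those regions over the box
    area (zero-area regions contribute nothing).  ``measure`` selects the
    default used by ``events_with_support`` but both columns are computed.
    """
    _check_measure(measure)
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one region")
    _require_annotations(regions)
    if box.area <= 0:
        raise ValueError("cost box has zero area")
    n = len(regions)
    counts: dict[Event, int] = {}
    areas: dict[Event, Fraction] = {}
    for region in regions:
        for event in region.common_events:  # type: ignore[union-attr]
            counts[event] = counts.get(event, 0) + 1
            areas[event] = areas.get(event, Fraction(0)) + region.area
    rows = tuple(
        SupportRow(
            event=event,
            region_count=counts[event],
            region_fraction=Fraction(counts[event], n),
            area_fraction=areas[event] / box.area,
        )
        for event in sorted(counts)
    )
    return SupportTable(rows=rows, n_regions=n, box_area=box.area)
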