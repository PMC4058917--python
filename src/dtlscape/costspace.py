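"""Partition of the (transfer-cost, loss-cost) plane into equivalence regions.

With the duplication cost normalized to 1, the cost of a front vector
v = ⟨δ, θ, ℓ⟩ at a point (C_T, C_L) is the affine function δ + C_T·θ + C_L·ℓ.
The region R(v) of a Pareto vector v is the subset of a user cost box on
which v is cost-minimal over the whole front: the intersection of the box
with one half-plane per competitor, hence a convex polygon that may
degenerate to a segment or a point.

All geometry is exact: vertices are intersections of lines with rational
coefficients, so every coordinate is a ``fractions.Fraction`` and the
dimension of a region (2, 1 or 0) is decided exactly, never by a floating
point tolerance.  Regions are closed, so boundary points belong to every
touching region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .dtl_model import Event, EventCountVector, EventCosts, reconciliation_cost
from .pareto_dp import AnnotatedFront

__all__ = [
    "CostBox",
    "Region",
    "RegionPartition",
    "partition_regions",
    "classify_region",
    "locate_point",
    "plot_regions",
]


def _frac(x) -> Fraction:
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


Point = tuple[Fraction, Fraction]


@dataclass(frozen=True)
class CostBox:
    """Rectangular range of transfer and loss costs, relative to the unit
    duplication cost.  All bounds strictly positive."""

    transfer_min: Fraction
    transfer_max: Fraction
    loss_min: Fraction
    loss_max: Fraction

    def __post_init__(self):
        for name in ("transfer_min", "transfer_max", "loss_min", "loss_max"):
            object.__setattr__(self, name, _frac(getattr(self, name)))
        if not (0 < self.transfer_min <= self.transfer_max):
            raise ValueError("need 0 < transfer_min <= transfer_max")
        if not (0 < self.loss_min <= self.loss_max):
            raise ValueError("need 0 < loss_min <= loss_max")

    def corners(self) -> list[Point]:
        """Counter-clockwise from (transfer_min, loss_min)."""
        return [
            (self.transfer_min, self.loss_min),
            (self.transfer_max, self.loss_min),
            (self.transfer_max, self.loss_max),
            (self.transfer_min, self.loss_max),
        ]

    @property
    def area(self) -> Fraction:
        return (self.transfer_max - self.transfer_min) * (self.loss_max - self.loss_min)

    def contains(self, point) -> bool:
        x, y = _frac(point[0]), _frac(point[1])
        return self.transfer_min <= x <= self.transfer_max and self.loss_min <= y <= self.loss_max


@dataclass(frozen=True)
class Region:
    """The optimality region of one Pareto vector inside a cost box."""

    vector: EventCountVector
    vertices: tuple[Point, ...]
    dimension: int
    area: Fraction
    count: int | None = None
    common_events: frozenset[Event] | None = field(default=None, compare=False)

    def contains(self, point) -> bool:
        """Exact membership test against the stored geometry."""
        p = (_frac(point[0]), _frac(point[1]))
        vs = self.vertices
        if self.dimension == 0:
            return p == vs[0]
        if self.dimension == 1:
            (ax, ay), (bx, by) = vs[0], vs[-1]
            if (bx - ax) * (p[1] - ay) != (by - ay) * (p[0] - ax):
                return False
            return min(ax, bx) <= p[0] <= max(ax, bx) and min(ay, by) <= p[1] <= max(ay, by)
        # convex CCW polygon: inside iff never strictly right of any edge
        for a, b in zip(vs, vs[1:] + vs[:1]):
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            if cross < 0:
                return False
        return True


@dataclass(frozen=True)
class RegionPartition:
    """All non-empty regions of a front within a box, plus the front vectors
    whose region does not intersect the box."""

    regions: tuple[Region, ...]
    empty_vectors: tuple[EventCountVector, ...]
    box: CostBox

    @property
    def zero_area_count(self) -> int:
        return sum(1 for r in self.regions if r.dimension < 2)


def _clip_halfplane(points: list[Point], a: Fraction, b: Fraction, c: Fraction) -> list[Point]:
    """Clip a convex polygon (CCW vertex list; may be degenerate) against the
    closed half-plane a·x + b·y + c <= 0."""
    if not points:
        return []

    def val(p: Point) -> Fraction:
        return a * p[0] + b * p[1] + c

    if len(points) == 1:
        return points if val(points[0]) <= 0 else []
    out: list[Point] = []
    n = len(points)
    for i in range(n):
        p, q = points[i], points[(i + 1) % n]
        vp, vq = val(p), val(q)
        if vp <= 0:
            out.append(p)
        if (vp < 0 < vq) or (vq < 0 < vp):
            t = vp / (vp - vq)
            out.append((p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])))
    # drop consecutive duplicates introduced by vertices lying on the line
    dedup: list[Point] = []
    for p in out:
        if not dedup or p != dedup[-1]:
            dedup.append(p)
    if len(dedup) > 1 and dedup[0] == dedup[-1]:
        dedup.pop()
    return dedup


def classify_region(vertices: list[Point]) -> tuple[int, Fraction, tuple[Point, ...]]:
    """Exact dimension (0 point / 1 segment / 2 polygon), shoelace area, and a
    canonical vertex tuple (duplicates and collinear run-throughs removed,
    CCW, lexicographically smallest vertex first)."""
    uniq: list[Point] = []
    for p in vertices:
        if p not in uniq:
            uniq.append(p)
    if not uniq:
        raise ValueError("empty vertex list")
    if len(uniq) == 1:
        return 0, Fraction(0), (uniq[0],)

    def cross(o: Point, u: Point, v: Point) -> Fraction:
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    collinear = all(cross(uniq[0], uniq[1], p) == 0 for p in uniq[2:])
    if collinear:
        lo, hi = min(uniq), max(uniq)
        return 1, Fraction(0), (lo, hi)
    # positive area: shoelace on the (CCW) cycle
    area2 = Fraction(0)
    n = len(uniq)
    for i in range(n):
        x1, y1 = uniq[i]
        x2, y2 = uniq[(i + 1) % n]
        area2 += x1 * y2 - x2 * y1
    if area2 < 0:  # defensive; clipping preserves CCW orientation
        uniq.reverse()
        area2 = -area2
    # remove vertices that are collinear with their neighbours
    slim = [
        p for i, p in enumerate(uniq)
        if cross(uniq[i - 1], p, uniq[(i + 1) % len(uniq)]) != 0
    ]
    start = slim.index(min(slim))
    canon = tuple(slim[start:] + slim[:start])
    return 2, area2 / 2, canon


def partition_regions(front: AnnotatedFront, box: CostBox) -> RegionPartition:
    """Intersect each front vector's optimality half-planes with the box.

    A vector v' competes with v through the half-plane
    (δ-δ') + C_T·(θ-θ') + C_L·(ℓ-ℓ') <= 0.  Vectors whose region misses the
    box are reported separately.  Output regions are sorted by area
    descending, then by vector, so runs are byte-stable.
    """
    entries = front.entries()
    if not entries:
        raise ValueError("cannot partition an empty front")
    regions: list[Region] = []
    empties: list[EventCountVector] = []
    for entry in entries:
        d, t, l = entry.vector
        poly = box.corners()
        for other in entries:
            if other.vector == entry.vector:
                continue
            d2, t2, l2 = other.vector
            poly = _clip_halfplane(poly, Fraction(t - t2), Fraction(l - l2), Fraction(d - d2))
            if not poly:
                break
        if not poly:
            empties.append(entry.vector)
            continue
        dim, area, canon = classify_region(poly)
        regions.append(
            Region(
                vector=entry.vector,
                vertices=canon,
                dimension=dim,
                area=area,
                count=entry.count,
                common_events=entry.events,
            )
        )
    regions.sort(key=lambda r: (-r.area, r.vector))
    return RegionPartition(regions=tuple(regions), empty_vectors=tuple(empties), box=box)


def locate_point(front: AnnotatedFront, point) -> list[EventCountVector]:
    """The set of front vectors that are cost-optimal at one (C_T, C_L) point
    (several on region boundaries).  Coordinates must be strictly positive."""
    x, y = _frac(point[0]), _frac(point[1])
    if x <= 0 or y <= 0:
        raise ValueError("event costs must be strictly positive")
    costs = EventCosts(transfer=x, loss=y)
    entries = front.entries()
    if not entries:
        raise ValueError("cannot locate a point against an empty front")
    values = [(reconciliation_cost(e.vector, costs), e.vector) for e in entries]
    best = min(v for v, _ in values)
    return sorted(vec for v, vec in values if v == best)


def plot_regions(partition: RegionPartition, path, gene_leaf_count: int | None = None) -> None:
    """Render the region map to an SVG/PNG file.

    The legend lists each region's event counts — including the implicit
    speciation count m - δ - θ - 1 when the gene-tree leaf count m is given —
    and the reconciliation count when tracked.  Colors are arbitrary; regions
    are legend-ordered by area descending.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab20")
    box = partition.box
    for i, region in enumerate(partition.regions):
        color = cmap(i % 20)
        pts = [(float(x), float(y)) for x, y in region.vertices]
        d, t, l = region.vector
        label = ""
        if gene_leaf_count is not None:
            label += f"s:{gene_leaf_count - d - t - 1} "
        label += f"d:{d} t:{t} l:{l}"
        if region.count is not None:
            label += f"  Count: {region.count}"
        if region.dimension == 2:
            ax.fill(*zip(*pts), color=color, alpha=0.8, label=label)
        elif region.dimension == 1:
            (x1, y1), (x2, y2) = pts[0], pts[-1]
            ax.plot([x1, x2], [y1, y2], color=color, linewidth=2.5, label=label)
        else:
            ax.plot(*pts[0], marker="o", color=color, label=label)
    ax.set_xlim(float(box.transfer_min), float(box.transfer_max))
    ax.set_ylim(float(box.loss_min), float(box.loss_max))
    ax.set_xlabel("transfer cost (relative to duplication)")
    ax.set_ylabel("loss cost (relative to duplication)")
    ax.legend(loc="center left", bbox_to_anchor=(1.02, 0.5), fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
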