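"""Permutation significance of reconciliation cost across the cost box.

For cophylogenetic data the null hypothesis is that the parasite tree tracks
the host tree no better than chance.  The tip association is permuted N times
and, at each cell centre of a grid over the (transfer-cost, loss-cost) box,
the observed optimal cost is compared with the N permuted optima:
p = (1 + #{permutations at most as costly}) / (N + 1), the add-one
permutation estimator, which never returns 0.

One Pareto front per permutation suffices for every grid cell, because the
fixed-cost optimum at any positive cost point is attained on the front; this
replaces a per-cell dynamic program and makes the grid resolution essentially
free compared with the permutations themselves.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from .dtl_model import EventCosts, min_cost_fixed, reconciliation_cost
from .pareto_dp import pareto_reconcile
from .costspace import CostBox
from .treeio import ReconInput

__all__ = [
    "SignificanceGrid",
    "permute_mapping",
    "significance_grid",
    "area_fractions",
]


@dataclass(frozen=True)
class SignificanceGrid:
    """Permutation p-values at the centres of a grid×grid tiling of the box.

    ``p_values[i][j]`` belongs to the cell centre
    (``transfer_centers[i]``, ``loss_centers[j]``); every p-value is an exact
    rational in (0, 1].
    """

    box: CostBox
    grid: int
    n_permutations: int
    seed: int
    mode: str
    transfer_centers: tuple[Fraction, ...]
    loss_centers: tuple[Fraction, ...]
    p_values: tuple[tuple[Fraction, ...], ...]


def permute_mapping(ri: ReconInput, mode: str = "shuffle", rng: random.Random | None = None) -> ReconInput:
    """A copy of the instance with its tip association randomized.

    ``shuffle`` permutes the existing species targets among the gene leaves
    (preserving the per-species tip-count multiset); ``uniform`` reassigns
    each gene leaf to a uniformly random species leaf.
    """
    if rng is None:
        rng = random.Random()
    genes = ri.gene_tree.leaf_labels  # fixed left-to-right order
    if mode == "shuffle":
        targets = [ri.mapping[g] for g in genes]
        rng.shuffle(targets)
    elif mode == "uniform":
        species = ri.species_tree.leaf_labels
        targets = [rng.choice(species) for _ in genes]
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    return ReconInput(
        species_tree=ri.species_tree,
        gene_tree=ri.gene_tree,
        mapping=dict(zip(genes, targets)),
    )


def _cell_centers(lo: Fraction, hi: Fraction, grid: int) -> tuple[Fraction, ...]:
    width = hi - lo
    return tuple(lo + width * Fraction(2 * i + 1, 2 * grid) for i in range(grid))


def _min_front_cost(vectors, costs: EventCosts) -> Fraction:
    return min(reconciliation_cost(v, costs) for v in vectors)


def significance_grid(
    ri: ReconInput,
    box: CostBox,
    grid: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "shuffle",
    engine: str = "front",
) -> SignificanceGrid:
    """Permutation p-values of the optimal reconciliation cost over the box.

    ``engine='front'`` computes one Pareto front per permutation and evaluates
    it at every cell; ``engine='fixed'`` recomputes the fixed-cost optimum at
    every cell by exhaustive enumeration and exists as a cross-check on tiny
    instances.  Both engines consume the permutation stream identically, so
    with equal seeds they see the same permuted instances.
    """
    if grid < 1 or n_permutations < 1:
        raise ValueError("grid and n_permutations must both be >= 1")
    if engine not in ("front", "fixed"):
        raise ValueError(f"unknown engine {engine!r}")
    rng = random.Random(seed)
    permuted = [permute_mapping(ri, mode, rng) for _ in range(n_permutations)]
    xs = _cell_centers(box.transfer_min, box.transfer_max, grid)
    ys = _cell_centers(box.loss_min, box.loss_max, grid)

    if engine == "front":
        observed = sorted(pareto_reconcile(ri, track_counts=False).vectors())
        # permuted instances frequently repeat the same front: deduplicate so
        # each distinct front is evaluated once per cell
        front_multiplicity: dict[tuple, int] = {}
        for inst in permuted:
            key = tuple(sorted(pareto_reconcile(inst, track_counts=False).vectors()))
            front_multiplicity[key] = front_multiplicity.get(key, 0) + 1
        rows = []
        for x in xs:
            row = []
            for y in ys:
                costs = EventCosts(transfer=x, loss=y)
                o = _min_front_cost(observed, costs)
                r = sum(
                    mult for key, mult in front_multiplicity.items()
                    if _min_front_cost(key, costs) <= o
                )
                row.append(Fraction(1 + r, n_permutations + 1))
            rows.append(tuple(row))
    else:
        rows = []
        for x in xs:
            row = []
            for y in ys:
                costs = EventCosts(transfer=x, loss=y)
                o, _ = min_cost_fixed(ri, costs, method="enumerate")
                r = sum(
                    1 for inst in permuted
                    if min_cost_fixed(inst, costs, method="enumerate")[0] <= o
                )
                row.append(Fraction(1 + r, n_permutations + 1))
            rows.append(tuple(row))

    return SignificanceGrid(
        box=box,
        grid=grid,
        n_permutations=n_permutations,
        seed=seed,
        mode=mode,
        transfer_centers=xs,
        loss_centers=ys,
        p_values=tuple(rows),
    )


def area_fractions(
    grid: SignificanceGrid, thresholds=(Fraction(1, 100), Fraction(1, 20))
) -> tuple[Fraction, Fraction, Fraction]:
    """Fractions of the box (cell-counted) with p < t1, t1 <= p < t2 and
    p >= t2; the three always sum to 1."""
    t1, t2 = (Fraction(str(t)) if isinstance(t, float) else Fraction(t) for t in thresholds)
    if not t1 < t2:
        raise ValueError("thresholds must be increasing")
    total = grid.grid * grid.grid
    strong = sum(1 for row in grid.p_values for p in row if p < t1)
    mid = sum(1 for row in grid.p_values for p in row if t1 <= p < t2)
    weak = total - strong - mid
    return Fraction(strong, total), Fraction(mid, total), Fraction(weak, total)


def plot_significance(grid: SignificanceGrid, path) -> None:
    """Heatmap of the p-value grid: green below 0.01, yellow between 0.01 and
    0.05, red at or above 0.05, brightness scaling with -log10(p)."""
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap  # noqa: F401  (kept simple)

    import numpy as np

    n = grid.grid
    rgb = np.zeros((n, n, 3))
    pmin = min(p for row in grid.p_values for p in row)
    max_mag = max(-math.log10(float(pmin)), 1.0)
    for i in range(n):
        for j in range(n):
            p = float(grid.p_values[i][j])
            bright = 0.35 + 0.65 * min(-math.log10(p) / max_mag, 1.0)
            if p < 0.01:
                base = (0.0, 1.0, 0.0)
            elif p < 0.05:
                base = (1.0, 1.0, 0.0)
            else:
                base = (1.0, 0.0, 0.0)
            rgb[n - 1 - j, i] = tuple(bright * c for c in base)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(
        rgb,
        extent=(
            float(grid.box.transfer_min), float(grid.box.transfer_max),
            float(grid.box.loss_min), float(grid.box.loss_max),
        ),
        aspect="auto",
    )
    ax.set_xlabel("transfer cost (relative to duplication)")
    ax.set_ylabel("loss cost (relative to duplication)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
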