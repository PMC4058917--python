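"""The duplication-transfer-loss (DTL) reconciliation model.

A DTL-scenario maps every node of the gene (parasite) tree T to a node of the
species (host) tree S and labels each internal gene node as a speciation,
duplication or transfer; losses are implied by the mapping.  Speciation is the
null event with cost 0; duplication, transfer and loss carry positive costs.

This module provides the scenario-level primitives (validity checking per the
seven-tuple definition, loss counting, event materialization, costs) plus two
correctness oracles: exhaustive scenario enumeration and fixed-cost
optimization.  The polynomial-time Pareto machinery lives in
:mod:`dtlscape.pareto_dp`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple

from .treeio import ReconInput, RootedBinaryTree, TreeNode

__all__ = [
    "EventCountVector",
    "EventCosts",
    "Event",
    "DTLScenario",
    "ValidityReport",
    "InstanceTooLargeError",
    "lca",
    "path_distance",
    "validate_scenario",
    "count_losses",
    "scenario_events",
    "scenario_event_vector",
    "reconciliation_cost",
    "enumerate_scenarios",
    "min_cost_fixed",
]


class EventCountVector(NamedTuple):
    """Event counts ⟨duplications, transfers, losses⟩ of a reconciliation.

    The number of speciations is implicit: for a gene tree with m leaves it is
    m - duplications - transfers - 1.
    """

    duplications: int
    transfers: int
    losses: int

    def __add__(self, other):  # type: ignore[override]
        return EventCountVector(
            self.duplications + other[0],
            self.transfers + other[1],
            self.losses + other[2],
        )

    def dominates(self, other: "EventCountVector") -> bool:
        """Strictly better: componentwise <= with at least one strict <."""
        return (
            self.duplications <= other.duplications
            and self.transfers <= other.transfers
            and self.losses <= other.losses
            and self != other
        )


def _to_fraction(x) -> Fraction:
    # str(float) round-trips the decimal literal the user typed, so 0.1 -> 1/10
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


@dataclass(frozen=True)
class EventCosts:
    """Positive event costs; speciation is free.  In normalized mode the
    duplication cost is 1 and transfer/loss are relative to it."""

    transfer: Fraction
    loss: Fraction
    duplication: Fraction = Fraction(1)

    def __post_init__(self):
        object.__setattr__(self, "transfer", _to_fraction(self.transfer))
        object.__setattr__(self, "loss", _to_fraction(self.loss))
        object.__setattr__(self, "duplication", _to_fraction(self.duplication))
        for name in ("duplication", "transfer", "loss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} cost must be strictly positive")


def reconciliation_cost(vector: EventCountVector, costs: EventCosts) -> Fraction:
    d, t, l = vector
    return costs.duplication * d + costs.transfer * t + costs.loss * l


@dataclass(frozen=True, order=True)
class Event:
    """A single reconciliation event under the most-specific identity.

    * speciation/duplication: gene node + species node it maps to;
    * transfer: additionally the recipient species node and the gene child on
      the transfer edge;
    * loss: the gene edge above ``gene`` together with the species edge
      (``species``, ``species_child``) on which the lineage is absent.
    """

    kind: str  # speciation | duplication | transfer | loss
    gene: str
    species: str
    recipient: str | None = None
    gene_child: str | None = None
    species_child: str | None = None

    def __post_init__(self):
        if self.kind not in ("speciation", "duplication", "transfer", "loss"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.recipient is not None) != (self.kind == "transfer"):
            raise ValueError("recipient is present iff the event is a transfer")
        if (self.species_child is not None) != (self.kind == "loss"):
            raise ValueError("species_child is present iff the event is a loss")

    def relaxed(self, identity: str = "species_mapping") -> tuple:
        """Coarser comparison keys: 'species_mapping' drops event types,
        'event_mapping' drops transfer recipients and loss branches."""
        if identity == "species_mapping":
            return (self.gene, self.species)
        if identity == "event_mapping":
            return (self.kind, self.gene, self.species)
        raise ValueError(f"unknown relaxed identity {identity!r}")


@dataclass(frozen=True)
class DTLScenario:
    """A DTL-scenario: node mapping M, the speciation/duplication/transfer
    partition of internal gene nodes, the transfer edges Ξ and recipients τ.

    All node references are labels; ``xi`` holds (parent, child) gene edges.
    """

    mapping: dict[str, str]
    sigma: frozenset[str]
    delta: frozenset[str]
    theta: frozenset[str]
    xi: frozenset[tuple[str, str]] = field(default=frozenset())
    tau: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "sigma", frozenset(self.sigma))
        object.__setattr__(self, "delta", frozenset(self.delta))
        object.__setattr__(self, "theta", frozenset(self.theta))
        object.__setattr__(self, "xi", frozenset(tuple(e) for e in self.xi))

    def label_of(self, gene: str) -> str:
        if gene in self.sigma:
            return "speciation"
        if gene in self.delta:
            return "duplication"
        if gene in self.theta:
            return "transfer"
        raise KeyError(f"{gene!r} is not a labelled internal node")


@dataclass(frozen=True)
class ValidityReport:
    ok: bool
    violations: tuple[str, ...]
    details: tuple[str, ...] = ()


class InstanceTooLargeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# basic tree operations (thin wrappers so the reconciliation API is uniform)


def lca(tree: RootedBinaryTree, nodes: Iterable[str | TreeNode]) -> TreeNode:
    """Last common ancestor: the unique smallest upper bound of the set."""
    return tree.lca(nodes)


def path_distance(tree: RootedBinaryTree, x: str | TreeNode, y: str | TreeNode) -> int:
    """Number of edges on the unique path between x and y (0 if x == y)."""
    return tree.distance(x, y)


# ---------------------------------------------------------------------------
# scenario validation


def _structural_check(ri: ReconInput, sc: DTLScenario) -> None:
    S, T = ri.species_tree, ri.gene_tree
    gene_labels = {n.label for n in T.postorder}
    internal = {n.label for n in T.internal_nodes}
    if set(sc.mapping) != gene_labels:
        extra = sorted(set(sc.mapping) - gene_labels)
        missing = sorted(gene_labels - set(sc.mapping))
        raise ValueError(
            f"scenario mapping must cover exactly the gene nodes "
            f"(extra: {extra}, missing: {missing})"
        )
    for s in sc.mapping.values():
        if s not in S:
            raise ValueError(f"scenario maps onto unknown species node {s!r}")
    labelled = set(sc.sigma) | set(sc.delta) | set(sc.theta)
    if labelled != internal or len(sc.sigma) + len(sc.delta) + len(sc.theta) != len(internal):
        raise ValueError("sigma/delta/theta must partition the internal gene nodes")
    gene_edges = {(n.label, c.label) for n in T.internal_nodes for c in n.children}
    for edge in sc.xi:
        if edge not in gene_edges:
            raise ValueError(f"transfer edge {edge} is not an edge of the gene tree")
    for t, r in sc.tau.items():
        if t not in gene_labels:
            raise ValueError(f"recipient given for unknown gene node {t!r}")
        if r not in S:
            raise ValueError(f"transfer recipient {r!r} is not a species node")


def validate_scenario(ri: ReconInput, sc: DTLScenario) -> ValidityReport:
    """Check a scenario against the seven-tuple constraints (1, 2a, 2b, 3,
    4a-4d).  Structural problems (dangling references, non-partition labels)
    raise ``ValueError``; model violations are reported."""
    _structural_check(ri, sc)
    S, T = ri.species_tree, ri.gene_tree
    M = sc.mapping
    violations: list[str] = []
    details: list[str] = []

    def violate(code: str, msg: str) -> None:
        if code not in violations:
            violations.append(code)
        details.append(f"{code}: {msg}")

    for leaf in T.leaves:
        if M[leaf.label] != ri.mapping[leaf.label]:
            violate("1", f"leaf {leaf.label} maps to {M[leaf.label]}, expected {ri.mapping[leaf.label]}")

    incomparable_edges: set[tuple[str, str]] = set()
    for t in T.internal_nodes:
        mt = M[t.label]
        child_images = []
        descendant_child = False
        for child in t.children:
            mc = M[child.label]
            child_images.append(mc)
            if S.is_ancestor(mc, mt) and mc != mt:
                violate("2a", f"M({t.label})={mt} is a proper descendant of M({child.label})={mc}")
            if S.is_ancestor(mt, mc):
                descendant_child = True
            if not S.comparable(mt, mc):
                incomparable_edges.add((t.label, child.label))
        if not descendant_child:
            violate("2b", f"no child image of {t.label} is a descendant of M({t.label})={mt}")

    if incomparable_edges != set(sc.xi):
        spurious = sorted(set(sc.xi) - incomparable_edges)
        absent = sorted(incomparable_edges - set(sc.xi))
        violate("3", f"transfer edges must be exactly the incomparable edges "
                     f"(spurious: {spurious}, missing: {absent})")

    for t in T.internal_nodes:
        mt = M[t.label]
        c1, c2 = t.children
        m1, m2 = M[c1.label], M[c2.label]
        label = sc.label_of(t.label)
        if label == "speciation":
            if S.comparable(m1, m2) or S.lca([m1, m2]).label != mt:
                violate("4a", f"{t.label} labelled speciation but M(t) != lca of incomparable child images")
        elif label == "duplication":
            anc = S.lca([m1, m2])
            if not S.is_ancestor(mt, anc.label):
                violate("4b", f"{t.label} labelled duplication but M(t) is not >= lca(child images)")
        has_transfer_edge = (t.label, c1.label) in sc.xi or (t.label, c2.label) in sc.xi
        if (label == "transfer") != has_transfer_edge:
            violate("4c", f"{t.label}: transfer label and incident transfer edges disagree")
        if label == "transfer":
            transfer_children = [c.label for c in t.children if (t.label, c.label) in sc.xi]
            if len(transfer_children) != 1 or t.label not in sc.tau:
                violate("4d", f"{t.label} needs exactly one transfer edge and a recipient")
            else:
                recipient = sc.tau[t.label]
                m_child = M[transfer_children[0]]
                if S.comparable(mt, recipient) or not S.is_ancestor(recipient, m_child):
                    violate("4d", f"{t.label}: recipient {recipient} must be incomparable to "
                                  f"M(t) and an ancestor of the transferred child's image")

    return ValidityReport(ok=not violations, violations=tuple(violations), details=tuple(details))


# ---------------------------------------------------------------------------
# losses and events


def _losses_along(
    S: RootedBinaryTree, gene_child: str, top: str | TreeNode, bottom: str | TreeNode
) -> list[Event]:
    """Loss events for a lineage (leading to ``gene_child``) that enters the
    species tree at ``top`` and survives only at ``bottom``: one loss on each
    sibling branch passed on the way down."""
    path = S.path_down(top, bottom)
    events = []
    for here, nxt in zip(path, path[1:]):
        lost_side = S.sibling(nxt)
        events.append(
            Event(kind="loss", gene=gene_child, species=here.label, species_child=lost_side.label)
        )
    return events


def count_losses(ri: ReconInput, sc: DTLScenario) -> tuple[int, list[Event]]:
    """Total number of losses of a valid scenario, with each loss materialized
    as an Event on a specific (gene edge, species edge) pair.

    Speciation at s: each child lineage enters the child of s on its side, so
    it pays distance-minus-one losses.  Duplication: both lineages start at s
    itself.  Transfer: the staying lineage starts at s, the transferred one at
    the recipient.
    """
    report = validate_scenario(ri, sc)
    if not report.ok:
        raise ValueError(f"invalid scenario: constraints {', '.join(report.violations)} violated")
    S, T = ri.species_tree, ri.gene_tree
    M = sc.mapping
    events: list[Event] = []
    for t in T.internal_nodes:
        s = M[t.label]
        c1, c2 = t.children
        label = sc.label_of(t.label)
        if label == "speciation":
            for child in (c1, c2):
                entry = next(c for c in S.node(s).children if S.is_ancestor(c, M[child.label]))
                events.extend(_losses_along(S, child.label, entry, M[child.label]))
        elif label == "duplication":
            for child in (c1, c2):
                events.extend(_losses_along(S, child.label, s, M[child.label]))
        else:  # transfer
            jump = c1 if (t.label, c1.label) in sc.xi else c2
            stay = c2 if jump is c1 else c1
            events.extend(_losses_along(S, stay.label, s, M[stay.label]))
            events.extend(_losses_along(S, jump.label, sc.tau[t.label], M[jump.label]))
    return len(events), events


def scenario_events(ri: ReconInput, sc: DTLScenario) -> frozenset[Event]:
    """All events of a valid scenario under the most-specific identity."""
    T = ri.gene_tree
    events: list[Event] = []
    for t in T.internal_nodes:
        label = sc.label_of(t.label)
        s = sc.mapping[t.label]
        if label == "transfer":
            jump = next(c.label for c in t.children if (t.label, c.label) in sc.xi)
            events.append(Event(kind="transfer", gene=t.label, species=s,
                                recipient=sc.tau[t.label], gene_child=jump))
        else:
            events.append(Event(kind=label, gene=t.label, species=s))
    _, losses = count_losses(ri, sc)
    events.extend(losses)
    return frozenset(events)


def scenario_event_vector(ri: ReconInput, sc: DTLScenario) -> EventCountVector:
    total, _ = count_losses(ri, sc)
    return EventCountVector(len(sc.delta), len(sc.theta), total)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


def enumerate_scenarios(
    ri: ReconInput, max_leaves: int = 6
) -> list[tuple[DTLScenario, EventCountVector]]:
    """Every distinct valid DTL-scenario, exhaustively.

    Scenario identity is (node mapping, event labels) with the canonical
    transfer recipient τ(t) = M(transfer child); a node whose children's
    images are incomparable with M(t) = lca may be labelled either speciation
    or duplication, and both labelings are returned as distinct scenarios.
    Intended as a test oracle for tiny instances only.
    """
    S, T = ri.species_tree, ri.gene_tree
    if len(T.leaves) > max_leaves or len(S.leaves) > max_leaves:
        raise InstanceTooLargeError(
            f"refusing to enumerate: instance exceeds {max_leaves} leaves per tree"
        )
    internal = T.internal_nodes
    species_nodes = S.postorder
    base = {leaf.label: ri.mapping[leaf.label] for leaf in T.leaves}
    results: list[tuple[DTLScenario, EventCountVector]] = []

    for assignment in itertools.product(species_nodes, repeat=len(internal)):
        M = dict(base)
        M.update({t.label: s.label for t, s in zip(internal, assignment)})
        ok = True
        xi: set[tuple[str, str]] = set()
        sigma_eligible: list[str] = []
        forced_theta: set[str] = set()
        tau: dict[str, str] = {}
        for t in internal:
            mt = M[t.label]
            c1, c2 = t.children
            m1, m2 = M[c1.label], M[c2.label]
            descendant = 0
            incomparable_children = []
            for child, mc in ((c1, m1), (c2, m2)):
                if S.is_ancestor(mc, mt) and mc != mt:
                    ok = False  # constraint 2a
                    break
                if S.is_ancestor(mt, mc):
                    descendant += 1
                else:
                    incomparable_children.append(child)
            if not ok:
                break
            if descendant == 0:
                ok = False  # constraint 2b
                break
            if incomparable_children:
                (jump,) = incomparable_children  # exactly one by 2a/2b
                xi.add((t.label, jump.label))
                forced_theta.add(t.label)
                tau[t.label] = M[jump.label]
            else:
                # both child images are descendants of mt; duplication is
                # always eligible, speciation additionally needs mt = lca of
                # incomparable child images
                if not S.comparable(m1, m2) and S.lca([m1, m2]).label == mt:
                    sigma_eligible.append(t.label)
        if not ok:
            continue
        free = sigma_eligible
        non_theta = [t.label for t in internal if t.label not in forced_theta]
        for choice in itertools.product((False, True), repeat=len(free)):
            sigma = {lab for lab, is_sigma in zip(free, choice) if is_sigma}
            delta = {lab for lab in non_theta if lab not in sigma}
            sc = DTLScenario(
                mapping=dict(M),
                sigma=frozenset(sigma),
                delta=frozenset(delta),
                theta=frozenset(forced_theta),
                xi=frozenset(xi),
                tau=dict(tau),
            )
            results.append((sc, scenario_event_vector(ri, sc)))
    return results


# ---------------------------------------------------------------------------
# fixed-cost optimization


def min_cost_fixed(
    ri: ReconInput, costs: EventCosts, method: str = "front"
) -> tuple[Fraction, int]:
    """Minimum reconciliation cost over all valid scenarios, and the number of
    scenarios attaining it.

    ``method='front'`` evaluates the Pareto front (for positive costs the
    optimum's vector is always on the front); ``method='enumerate'`` brute
    forces tiny instances and exists as an independent cross-check.
    """
    if method == "enumerate":
        best: Fraction | None = None
        count = 0
        for _, vector in enumerate_scenarios(ri):
            c = reconciliation_cost(vector, costs)
            if best is None or c < best:
                best, count = c, 1
            elif c == best:
                count += 1
        assert best is not None  # every instance admits at least one scenario
        return best, count
    if method == "front":
        from .pareto_dp import pareto_reconcile

        front = pareto_reconcile(ri, track_counts=True)
        best = min(reconciliation_cost(e.vector, costs) for e in front.entries())
        count = sum(
            e.count for e in front.entries()
            if reconciliation_cost(e.vector, costs) == best
        )
        return best, count
    raise ValueError(f"unknown method {method!r}; use 'front' or 'enumerate'")
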