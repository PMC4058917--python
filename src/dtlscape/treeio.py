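"""Input/output for tanglegrams: rooted binary trees, tip mappings, results.

Trees are purely topological: Newick branch lengths and internal labels are
accepted on input and discarded.  The reconciliation model never consults
branch lengths, so none are stored.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "MappingError",
    "TreeNode",
    "RootedBinaryTree",
    "ReconInput",
    "parse_newick",
    "tree_from_nested",
    "parse_mapping",
    "read_recon_input",
    "read_combined_input",
    "serialize_results",
    "front_from_json",
]


class TreeError(ValueError):
    """Base class for tree/mapping input errors."""


class NewickParseError(TreeError):
    pass


class MappingError(TreeError):
    pass


class TreeNode:
    """A node of a rooted binary tree.

    Leaves carry the user-supplied label; internal nodes are auto-named
    ``"<min leaf of left>+<min leaf of right>"``, which is unique within a
    tree because leaf labels are.
    """

    __slots__ = ("label", "children", "parent", "depth", "index", "_tin", "_tout")

    def __init__(self, label: str, children: tuple["TreeNode", ...] = ()):
        self.label = label
        self.children = children
        self.parent: TreeNode | None = None
        self.depth = 0
        self.index = -1  # postorder index
        self._tin = -1
        self._tout = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r})"


class RootedBinaryTree:
    """Rooted binary tree with O(1) ancestor tests and label lookup.

    Invariants: every internal node has exactly two children; leaf labels are
    unique; node count equals ``2 * leaf count - 1``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.postorder: list[TreeNode] = []
        self.leaves: list[TreeNode] = []
        self._by_label: dict[str, TreeNode] = {}
        self._index(root)

    def _index(self, root: TreeNode) -> None:
        # iterative DFS assigning depth, Euler intervals, postorder indices
        timer = 0
        stack: list[tuple[TreeNode, bool]] = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                node._tout = timer
                timer += 1
                node.index = len(self.postorder)
                self.postorder.append(node)
                continue
            node._tin = timer
            timer += 1
            stack.append((node, True))
            for child in reversed(node.children):
                child.parent = node
                child.depth = node.depth + 1
                stack.append((child, False))
        for node in self.postorder:
            if node.is_leaf:
                self.leaves.append(node)
        self.leaves.sort(key=lambda n: n._tin)  # left-to-right order
        for node in self.postorder:
            if len(node.children) not in (0, 2):
                raise NewickParseError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "trees must be strictly binary"
                )
            if node.label in self._by_label:
                raise NewickParseError(f"duplicate node label {node.label!r}")
            self._by_label[node.label] = node

    # -- lookups -----------------------------------------------------------

    def node(self, ref: "str | TreeNode") -> TreeNode:
        if isinstance(ref, TreeNode):
            if self._by_label.get(ref.label) is not ref:
                raise KeyError(f"node {ref.label!r} does not belong to this tree")
            return ref
        try:
            return self._by_label[ref]
        except KeyError:
            raise KeyError(f"no node labelled {ref!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves]

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder if not n.is_leaf]

    # -- order relations ---------------------------------------------------

    def is_ancestor(self, anc: "str | TreeNode", des: "str | TreeNode") -> bool:
        """True iff ``anc`` lies on the path from the root to ``des``.

        Every node is an ancestor (and descendant) of itself.
        """
        a, d = self.node(anc), self.node(des)
        return a._tin <= d._tin and d._tout <= a._tout

    def comparable(self, x: "str | TreeNode", y: "str | TreeNode") -> bool:
        return self.is_ancestor(x, y) or self.is_ancestor(y, x)

    def lca(self, refs: Iterable["str | TreeNode"]) -> TreeNode:
        nodes = [self.node(r) for r in refs]
        if not nodes:
            raise ValueError("lca of an empty node set is undefined")
        cur = nodes[0]
        for other in nodes[1:]:
            while not self.is_ancestor(cur, other):
                assert cur.parent is not None
                cur = cur.parent
        return cur

    def distance(self, x: "str | TreeNode", y: "str | TreeNode") -> int:
        """Number of edges on the unique path between ``x`` and ``y``."""
        a, b = self.node(x), self.node(y)
        anc = self.lca([a, b])
        return (a.depth - anc.depth) + (b.depth - anc.depth)

    def sibling(self, ref: "str | TreeNode") -> TreeNode:
        node = self.node(ref)
        if node.parent is None:
            raise ValueError("the root has no sibling")
        c1, c2 = node.parent.children
        return c2 if c1 is node else c1

    def path_down(self, top: "str | TreeNode", bottom: "str | TreeNode") -> list[TreeNode]:
        """Nodes on the root-ward path from ``top`` down to ``bottom`` inclusive."""
        t, b = self.node(top), self.node(bottom)
        if not self.is_ancestor(t, b):
            raise ValueError(f"{t.label!r} is not an ancestor of {b.label!r}")
        rev = []
        cur = b
        while cur is not t:
            rev.append(cur)
            assert cur.parent is not None
            cur = cur.parent
        rev.append(t)
        return rev[::-1]

    def subtree_nodes(self, ref: "str | TreeNode") -> list[TreeNode]:
        top = self.node(ref)
        return [n for n in self.postorder if self.is_ancestor(top, n)]

    def incomparable_nodes(self, ref: "str | TreeNode") -> list[TreeNode]:
        node = self.node(ref)
        return [n for n in self.postorder if not self.comparable(node, n)]

    # -- output ------------------------------------------------------------

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            left, right = node.children
            return f"({fmt(left)},{fmt(right)})"

        return fmt(self.root) + ";"

    def __len__(self) -> int:
        return len(self.postorder)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedBinaryTree):
            return NotImplemented
        return self._shape(self.root) == other._shape(other.root)

    def __hash__(self):  # pragma: no cover - trees used as values, not keys
        return hash(self._shape(self.root))

    @classmethod
    def _shape(cls, node: TreeNode):
        if node.is_leaf:
            return node.label
        return tuple(sorted((cls._shape(c) for c in node.children), key=repr))


def _min_leaf(node: TreeNode) -> str:
    if node.is_leaf:
        return node.label
    return min(_min_leaf(c) for c in node.children)


def _name_internals(node: TreeNode, taken: set[str]) -> None:
    if node.is_leaf:
        return
    for child in node.children:
        _name_internals(child, taken)
    left, right = node.children
    name = f"{_min_leaf(left)}+{_min_leaf(right)}"
    while name in taken:
        name += "'"
    node.label = name
    taken.add(name)


def tree_from_nested(nested) -> RootedBinaryTree:
    """Build a tree from nested 2-tuples of leaf-label strings.

    ``tree_from_nested((("A", "B"), "C"))`` gives the caterpillar ((A,B),C).
    A bare string gives a single-leaf tree.
    """

    def build(spec) -> TreeNode:
        if isinstance(spec, str):
            return TreeNode(spec)
        if len(spec) != 2:
            raise NewickParseError(f"internal nodes need exactly 2 children, got {len(spec)}")
        return TreeNode("", tuple(build(s) for s in spec))

    root = build(nested)
    leaves = set()

    def collect(n: TreeNode):
        if n.is_leaf:
            if n.label in leaves:
                raise NewickParseError(f"duplicate leaf label {n.label!r}")
            leaves.add(n.label)
        for c in n.children:
            collect(c)

    collect(root)
    _name_internals(root, set(leaves))
    return RootedBinaryTree(root)


def parse_newick(text: str) -> RootedBinaryTree:
    """Parse a single rooted Newick string into a :class:`RootedBinaryTree`.

    Branch lengths and internal node labels are discarded.  Redundant outer
    parentheses (a unary wrapper above the root) are collapsed; any other
    unary node, any polytomy, and duplicate leaf labels are errors.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several exception types
        raise NewickParseError(f"malformed Newick string: {exc}") from exc

    seed = dtree.seed_node
    # collapse redundant outer parentheses: unary chain above the true root
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]

    def convert(dnode) -> TreeNode:
        kids = dnode.child_nodes()
        if not kids:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if not label:
                raise NewickParseError("leaf without a label")
            return TreeNode(str(label))
        if len(kids) == 1:
            raise NewickParseError(
                f"unary internal node (child: {_describe(kids[0])}); trees must be binary"
            )
        if len(kids) > 2:
            raise NewickParseError(
                f"polytomy with {len(kids)} children at node {_describe(dnode)}"
            )
        return TreeNode("", tuple(convert(k) for k in kids))

    root = convert(seed)
    leaves: list[str] = []

    def collect(n: TreeNode):
        if n.is_leaf:
            leaves.append(n.label)
        for c in n.children:
            collect(c)

    collect(root)
    dupes = sorted({lab for lab in leaves if leaves.count(lab) > 1})
    if dupes:
        raise NewickParseError(f"duplicate leaf labels: {', '.join(dupes)}")
    _name_internals(root, set(leaves))
    return RootedBinaryTree(root)


def _describe(dnode) -> str:
    if dnode.taxon is not None:
        return repr(dnode.taxon.label)
    if dnode.label:
        return repr(dnode.label)
    kids = dnode.child_nodes()
    return f"<internal, {len(kids)} children>" if kids else "<unnamed leaf>"


# ---------------------------------------------------------------------------
# tip mapping


@dataclass(frozen=True)
class ReconInput:
    """A reconciliation problem instance: species tree S, gene tree T, and a
    total leaf mapping from the leaves of T onto the leaves of S."""

    species_tree: RootedBinaryTree
    gene_tree: RootedBinaryTree
    mapping: dict[str, str] = field(compare=False)

    def __post_init__(self):
        gene_leaves = set(self.gene_tree.leaf_labels)
        species_leaves = set(self.species_tree.leaf_labels)
        unknown = sorted(set(self.mapping) - gene_leaves)
        if unknown:
            raise MappingError(f"mapped labels not in gene tree: {', '.join(unknown)}")
        missing = sorted(gene_leaves - set(self.mapping))
        if missing:
            raise MappingError(f"unmapped gene leaves: {', '.join(missing)}")
        bad = sorted(t for t in self.mapping.values() if t not in species_leaves)
        if bad:
            raise MappingError(f"unknown species leaves: {', '.join(sorted(set(bad)))}")


def parse_mapping(
    text: str,
    gene_tree: RootedBinaryTree,
    species_tree: RootedBinaryTree,
) -> dict[str, str]:
    """Parse a tip-association table: one ``gene<TAB>species`` pair per line.

    A ``:`` separator is also accepted; ``#`` starts a comment.  The mapping
    must be total over the gene leaves; many gene leaves may map to the same
    species leaf.
    """
    pairs: dict[str, str] = {}
    duplicates: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "\t" in line:
            parts = line.split("\t")
        elif ":" in line:
            parts = line.split(":")
        else:
            parts = line.split()
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise MappingError(f"line {lineno}: expected 'gene<TAB>species', got {raw!r}")
        gene, species = parts
        if gene in pairs:
            duplicates.append(gene)
        pairs[gene] = species
    errors = []
    if duplicates:
        errors.append(f"duplicate gene-leaf lines: {', '.join(sorted(set(duplicates)))}")
    unknown_species = sorted({s for s in pairs.values() if s not in set(species_tree.leaf_labels)})
    if unknown_species:
        errors.append(f"unknown species leaves: {', '.join(unknown_species)}")
    gene_leaves = set(gene_tree.leaf_labels)
    unknown_genes = sorted(set(pairs) - gene_leaves)
    if unknown_genes:
        errors.append(f"unknown gene leaves: {', '.join(unknown_genes)}")
    missing = sorted(gene_leaves - set(pairs))
    if missing:
        errors.append(f"unmapped gene leaves: {', '.join(missing)}")
    if errors:
        raise MappingError("; ".join(errors))
    return pairs


def read_recon_input(host_path, parasite_path, mapping_path) -> ReconInput:
    """Read a problem instance from three files (host tree, parasite tree,
    tip mapping)."""
    with open(host_path) as fh:
        species = parse_newick(fh.read())
    with open(parasite_path) as fh:
        gene = parse_newick(fh.read())
    with open(mapping_path) as fh:
        mapping = parse_mapping(fh.read(), gene, species)
    return ReconInput(species_tree=species, gene_tree=gene, mapping=mapping)


_SECTIONS = ("HOSTTREE", "PARASITETREE", "MAPPING")


def read_combined_input(path) -> ReconInput:
    """Read a single file with ``HOSTTREE`` / ``PARASITETREE`` / ``MAPPING``
    section headers (each on its own line)."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for raw in fh:
            word = raw.strip().upper()
            if word in _SECTIONS:
                current = word
                sections.setdefault(current, [])
                continue
            if current is not None:
                sections[current].append(raw.rstrip("\n"))
    missing = [s for s in _SECTIONS if s not in sections]
    if missing:
        raise TreeError(f"combined input file lacks sections: {', '.join(missing)}")
    species = parse_newick("\n".join(sections["HOSTTREE"]))
    gene = parse_newick("\n".join(sections["PARASITETREE"]))
    mapping = parse_mapping("\n".join(sections["MAPPING"]), gene, species)
    return ReconInput(species_tree=species, gene_tree=gene, mapping=mapping)


def write_recon_input(ri: ReconInput, host_path, parasite_path, mapping_path) -> None:
    with open(host_path, "w") as fh:
        fh.write(ri.species_tree.newick() + "\n")
    with open(parasite_path, "w") as fh:
        fh.write(ri.gene_tree.newick() + "\n")
    with open(mapping_path, "w") as fh:
        for gene in ri.gene_tree.leaf_labels:
            fh.write(f"{gene}\t{ri.mapping[gene]}\n")


# ---------------------------------------------------------------------------
# result serialization


def _frac_str(x: Fraction) -> str:
    return f"{x.numerator}/{x.denominator}" if x.denominator != 1 else str(x.numerator)


def _event_dict(event) -> dict:
    d = {"kind": event.kind, "gene": event.gene, "species": event.species}
    if event.recipient is not None:
        d["recipient"] = event.recipient
    if event.gene_child is not None:
        d["gene_child"] = event.gene_child
    if event.species_child is not None:
        d["species_child"] = event.species_child
    return d


def _front_records(front) -> list[dict]:
    records = []
    for entry in front.entries():
        rec: dict = {"vector": list(entry.vector)}
        if entry.count is not None:
            rec["count"] = entry.count
        if entry.events is not None:
            rec["events"] = [_event_dict(e) for e in sorted(entry.events)]
        records.append(rec)
    return records


def _region_records(regions) -> list[dict]:
    records = []
    for region in regions:
        rec: dict = {
            "vector": list(region.vector),
            "dimension": region.dimension,
            "area": _frac_str(region.area),
            "vertices": [[_frac_str(x), _frac_str(y)] for x, y in region.vertices],
        }
        if region.count is not None:
            rec["count"] = region.count
        if region.common_events is not None:
            rec["events"] = [_event_dict(e) for e in sorted(region.common_events)]
        records.append(rec)
    return records


def _grid_record(grid) -> dict:
    return {
        "grid": grid.grid,
        "n_permutations": grid.n_permutations,
        "seed": grid.seed,
        "mode": grid.mode,
        "transfer_centers": [_frac_str(x) for x in grid.transfer_centers],
        "loss_centers": [_frac_str(y) for y in grid.loss_centers],
        "p_values": [[_frac_str(p) for p in row] for row in grid.p_values],
    }


def _support_records(table) -> list[dict]:
    return [
        {
            "event": _event_dict(row.event),
            "region_count": row.region_count,
            "region_fraction": _frac_str(row.region_fraction),
            "area_fraction": _frac_str(row.area_fraction),
        }
        for row in table.rows
    ]


def serialize_results(obj, format: str = "json") -> str:
    """Serialize a result object (annotated front, region list/partition,
    significance grid, or support table) to JSON or CSV text."""
    if format not in ("json", "csv"):
        raise ValueError(f"unsupported format {format!r}; use 'json' or 'csv'")

    from .costspace import Region, RegionPartition
    from .events_consensus import SupportTable
    from .pareto_dp import AnnotatedFront
    from .significance import SignificanceGrid

    if isinstance(obj, AnnotatedFront):
        payload: object = {"type": "pareto_front", "entries": _front_records(obj)}
        rows = [
            {"duplications": e.vector[0], "transfers": e.vector[1], "losses": e.vector[2],
             "count": e.count if e.count is not None else ""}
            for e in obj.entries()
        ]
        header = ["duplications", "transfers", "losses", "count"]
    elif isinstance(obj, RegionPartition) or (
        isinstance(obj, (list, tuple)) and all(isinstance(r, Region) for r in obj)
    ):
        regions = obj.regions if isinstance(obj, RegionPartition) else list(obj)
        payload = _region_records(regions)
        if isinstance(obj, RegionPartition):
            payload = {
                "type": "region_partition",
                "box": {
                    "transfer": [_frac_str(obj.box.transfer_min), _frac_str(obj.box.transfer_max)],
                    "loss": [_frac_str(obj.box.loss_min), _frac_str(obj.box.loss_max)],
                },
                "regions": payload,
                "empty_vectors": [list(v) for v in obj.empty_vectors],
            }
        rows = [
            {"duplications": r.vector[0], "transfers": r.vector[1], "losses": r.vector[2],
             "dimension": r.dimension, "area": _frac_str(r.area),
             "count": r.count if r.count is not None else ""}
            for r in regions
        ]
        header = ["duplications", "transfers", "losses", "dimension", "area", "count"]
    elif isinstance(obj, SignificanceGrid):
        payload = _grid_record(obj)
        rows = [
            {"transfer_cost": _frac_str(x), "loss_cost": _frac_str(y),
             "p_value": _frac_str(obj.p_values[i][j])}
            for i, x in enumerate(obj.transfer_centers)
            for j, y in enumerate(obj.loss_centers)
        ]
        header = ["transfer_cost", "loss_cost", "p_value"]
    elif isinstance(obj, SupportTable):
        payload = {"type": "support_table", "rows": _support_records(obj)}
        rows = [
            {"kind": r.event.kind, "gene": r.event.gene, "species": r.event.species,
             "recipient": r.event.recipient or "", "gene_child": r.event.gene_child or "",
             "species_child": r.event.species_child or "",
             "region_count": r.region_count,
             "region_fraction": _frac_str(r.region_fraction),
             "area_fraction": _frac_str(r.area_fraction)}
            for r in table_rows(obj)
        ]
        header = ["kind", "gene", "species", "recipient", "gene_child", "species_child",
                  "region_count", "region_fraction", "area_fraction"]
    else:
        raise ValueError(f"cannot serialize object of type {type(obj).__name__}")

    if format == "json":
        return json.dumps(payload, indent=2, sort_keys=False)
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=header)
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def table_rows(table) -> Sequence:
    return table.rows


def front_from_json(text: str):
    """Inverse of :func:`serialize_results` for annotated fronts."""
    from .dtl_model import Event, EventCountVector
    from .pareto_dp import AnnotatedFront, AnnotatedVector

    payload = json.loads(text)
    if not isinstance(payload, dict) or payload.get("type") != "pareto_front":
        raise ValueError("not a serialized Pareto front")
    entries = []
    for rec in payload["entries"]:
        vector = EventCountVector(*rec["vector"])
        events = None
        if "events" in rec:
            events = frozenset(
                Event(
                    kind=e["kind"],
                    gene=e["gene"],
                    species=e["species"],
                    recipient=e.get("recipient"),
                    gene_child=e.get("gene_child"),
                    species_child=e.get("species_child"),
                )
                for e in rec["events"]
            )
        entries.append(AnnotatedVector(vector=vector, count=rec.get("count"), events=events))
    return AnnotatedFront(entries)
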