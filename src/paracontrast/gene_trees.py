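"""Gene-tree data model, Newick/NHX input/output, node metrics and tree filters.

Gene trees here are rooted, binary, time-calibrated trees whose internal
nodes are tagged with the evolutionary event that created them: a speciation,
a gene duplication, or "NA" (unresolved / dubious nodes).  Branch lengths are
in million years (My).  Tips carry gene identifiers that key into a trait
table (e.g. tissue-specificity tau of each gene's expression).

Events are encoded on the wire as NHX comments on internal nodes:
``[&&NHX:Ev=spec]``, ``[&&NHX:Ev=dup]``, ``[&&NHX:Ev=na]``; the common
``D=Y`` / ``D=N`` duplication flags are also accepted.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Event",
    "Node",
    "GeneTree",
    "TraitTable",
    "NodeMetrics",
    "ParseError",
    "AnnotationError",
    "read_trees",
    "read_trait_table",
    "write_trees",
    "node_metrics",
    "classify_duplication_ages",
    "max_speciation_age",
    "relabel_duplicate_speciation_labels",
    "filter_trees",
    "prune_to_trait_tips",
]

ULTRAMETRIC_RTOL = 1e-6


class Event(enum.Enum):
    """Evolutionary event at an internal node of a gene tree."""

    SPECIATION = "speciation"
    DUPLICATION = "duplication"
    NA_EVENT = "na"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ParseError(ValueError):
    """Malformed Newick input."""


class AnnotationError(ValueError):
    """Unknown or inconsistent node-event annotation."""


# token -> Event for the Ev= NHX key
_EV_TOKENS = {
    "spec": Event.SPECIATION,
    "speciation": Event.SPECIATION,
    "dup": Event.DUPLICATION,
    "duplication": Event.DUPLICATION,
    "na": Event.NA_EVENT,
}
_EV_OUT = {Event.SPECIATION: "spec", Event.DUPLICATION: "dup", Event.NA_EVENT: "na"}


class Node:
    """One node of a :class:`GeneTree`.

    ``length`` is the branch length to the parent (``None`` at the root).
    ``event`` is set on internal nodes only; ``label`` on tips (and may hold
    a clade name on internal nodes).
    """

    __slots__ = ("id", "parent", "children", "length", "label", "event", "clade")

    def __init__(self, length=None, label=None, event=None, clade=None):
        self.id: int = -1
        self.parent: "Node | None" = None
        self.children: list[Node] = []
        self.length: float | None = length
        self.label: str | None = label
        self.event: Event | None = event
        self.clade: str | None = clade

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.label if self.is_tip else (self.event and self.event.value)
        return f"Node(id={self.id}, {kind}, len={self.length})"


class GeneTree:
    """Rooted binary gene tree with event-tagged internal nodes.

    Node ids are consecutive integers assigned in postorder at construction;
    they are stable until the topology is modified (pruning reindexes).
    """

    def __init__(self, root: Node, tree_id: str | None = None,
                 ultrametric: bool = True):
        self.root = root
        self.tree_id = tree_id
        #: set False by operations that deliberately break the time
        #: calibration (bias injection, branch-length transformation)
        self.ultrametric_expected = ultrametric
        self._index()

    # -- structure ---------------------------------------------------------

    def _index(self) -> None:
        self._postorder: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                self._postorder.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        for i, node in enumerate(self._postorder):
            node.id = i

    def postorder(self) -> Sequence[Node]:
        return self._postorder

    def preorder(self) -> Iterator[Node]:
        return reversed(self._postorder)

    @property
    def nodes(self) -> Sequence[Node]:
        return self._postorder

    @property
    def tips(self) -> list[Node]:
        return [n for n in self._postorder if n.is_tip]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self._postorder if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self._postorder if n.is_tip)

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    def check_binary(self) -> None:
        for n in self.internal_nodes:
            if len(n.children) != 2:
                raise ParseError(
                    f"tree {self.tree_id!r}: node with {len(n.children)} "
                    "children; only strictly binary trees are supported"
                )

    # -- geometry ----------------------------------------------------------

    def heights(self) -> dict[int, float]:
        """Distance of every node from the root, in My."""
        h: dict[int, float] = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            h[node.id] = h[node.parent.id] + (node.length or 0.0)
        return h

    @property
    def height(self) -> float:
        h = self.heights()
        return max(h[t.id] for t in self.tips)

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        h = self.heights()
        tip_h = [h[t.id] for t in self.tips]
        top = max(tip_h)
        if top <= 0:
            return True
        return (top - min(tip_h)) <= rtol * top

    def has_negative_branches(self) -> bool:
        return any(n.length is not None and n.length < 0
                   for n in self._postorder if n is not self.root)

    # -- copying / serialisation ------------------------------------------

    def copy(self) -> "GeneTree":
        def rec(node: Node) -> Node:
            new = Node(length=node.length, label=node.label,
                       event=node.event, clade=node.clade)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return GeneTree(rec(self.root), tree_id=self.tree_id,
                        ultrametric=self.ultrametric_expected)

    def to_newick(self) -> str:
        out = io.StringIO()

        def rec(node: Node) -> None:
            if node.is_tip:
                out.write(_quote_label(node.label or ""))
            else:
                out.write("(")
                for i, c in enumerate(node.children):
                    if i:
                        out.write(",")
                    rec(c)
                out.write(")")
                if node.clade:
                    out.write(_quote_label(node.clade))
                if node.event is not None:
                    out.write(f"[&&NHX:Ev={_EV_OUT[node.event]}]")
            if node.length is not None:
                out.write(f":{float(node.length)!r}")

        rec(self.root)
        out.write(";")
        return out.getvalue()


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "();:,[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TraitTable:
    """Map tip label -> trait value for a univariate continuous character.

    Empirical tissue-specificity tau lies in [0, 1]; simulated traits are
    unbounded.  Missing tips are simply absent from ``values``.
    """

    values: dict[str, float]
    name: str = "trait"

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, labels: Iterable[str]) -> "TraitTable":
        return TraitTable({k: self.values[k] for k in labels if k in self.values},
                          name=self.name)


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node placement on the time axis.

    age: My from the node down to its tips (mean tip distance if the tree is
    not ultrametric); height: My from the root; depth: nodes on the root
    path (root = 0).
    """

    age: float
    height: float
    depth: int


# ---------------------------------------------------------------------------
# input / output
# ---------------------------------------------------------------------------

def _event_from_comments(comments: list[str]) -> Event | None:
    for comment in comments:
        body = comment.lstrip("&")
        if body.upper().startswith("NHX"):
            body = body[3:]
        for item in body.split(":"):
            if not item or "=" not in item:
                continue
            key, _, val = item.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "Ev":
                ev = _EV_TOKENS.get(val.lower())
                if ev is None:
                    raise AnnotationError(f"unknown event token {val!r}")
                return ev
            if key == "D":
                if val.upper() == "Y":
                    return Event.DUPLICATION
                if val.upper() == "N":
                    return Event.SPECIATION
                raise AnnotationError(f"unknown duplication flag D={val!r}")
    return None


def read_trees(source, default_event: Event = Event.NA_EVENT,
               tree_id_prefix: str = "tree") -> list[GeneTree]:
    """Read one or more Newick/NHX records into :class:`GeneTree` objects.

    ``source`` is a path or a string of Newick text.  Internal nodes without
    an event annotation default to ``NA_EVENT``; the number of such defaults
    is counted on each tree as ``tree.n_unannotated``.
    """
    if isinstance(source, str) and ("(" in source or ";" in source):
        kwargs = {"data": source}
    else:
        kwargs = {"path": str(source)}
    try:
        dtrees = dendropy.TreeList.get(
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
            preserve_underscores=True,
            **kwargs,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"malformed Newick input: {exc}") from exc

    trees: list[GeneTree] = []
    for i, dt in enumerate(dtrees):
        root = _convert_dendropy(dt.seed_node, default_event)
        tree = GeneTree(root, tree_id=f"{tree_id_prefix}{i}")
        tree.n_unannotated = _count_defaults(dt.seed_node)
        tree.check_binary()
        trees.append(tree)
    if not trees:
        raise ParseError("no Newick records found in input")
    return trees


def _convert_dendropy(dnode, default_event: Event) -> Node:
    if not dnode.child_nodes():
        label = dnode.taxon.label if dnode.taxon else dnode.label
        return Node(length=dnode.edge.length, label=label)
    event = _event_from_comments(dnode.comments)
    node = Node(length=dnode.edge.length,
                event=default_event if event is None else event,
                clade=dnode.label)
    for c in dnode.child_nodes():
        node.add_child(_convert_dendropy(c, default_event))
    return node


def _count_defaults(dnode) -> int:
    n = 0
    for nd in dnode.preorder_iter():
        if nd.child_nodes() and _event_from_comments(nd.comments) is None:
            n += 1
    return n


def write_trees(trees: Iterable[GeneTree], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")


def read_trait_table(path, name: str = "trait") -> TraitTable:
    """Read a two-column TSV ``tip_id<TAB>value``; a header row is optional."""
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"trait table line {i + 1}: expected 2 columns")
            try:
                values[parts[0]] = float(parts[1])
            except ValueError:
                if i == 0:  # header row
                    continue
                raise ParseError(
                    f"trait table line {i + 1}: non-numeric value {parts[1]!r}"
                ) from None
    return TraitTable(values, name=name)


def write_trait_table(traits: TraitTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"tip_id\t{traits.name}\n")
        for k, v in traits.values.items():
            fh.write(f"{k}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# node metrics and event age classes
# ---------------------------------------------------------------------------

def node_metrics(tree: GeneTree) -> dict[int, NodeMetrics]:
    """Age (to tips), height (from root) and depth (node count) per node.

    On a non-ultrametric tree the age of a node is the mean distance to its
    descendant tips.
    """
    heights = tree.heights()
    # mean distance to descendant tips, postorder accumulation
    n_desc: dict[int, int] = {}
    sum_dist: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            n_desc[node.id] = 1
            sum_dist[node.id] = 0.0
        else:
            n_desc[node.id] = sum(n_desc[c.id] for c in node.children)
            sum_dist[node.id] = sum(
                sum_dist[c.id] + n_desc[c.id] * (c.length or 0.0)
                for c in node.children
            )
    depth: dict[int, int] = {tree.root.id: 0}
    for node in tree.preorder():
        if node is not tree.root:
            depth[node.id] = depth[node.parent.id] + 1
    return {
        node.id: NodeMetrics(
            age=0.0 if node.is_tip else sum_dist[node.id] / n_desc[node.id],
            height=heights[node.id],
            depth=depth[node.id],
        )
        for node in tree.postorder()
    }


def max_speciation_age(trees: Sequence[GeneTree]) -> float:
    """Maximum age of any speciation node over a set of trees."""
    best = None
    for tree in trees:
        metrics = node_metrics(tree)
        for node in tree.internal_nodes:
            if node.event is Event.SPECIATION:
                age = metrics[node.id].age
                best = age if best is None else max(best, age)
    if best is None:
        raise ValueError("no speciation nodes in the tree set; "
                         "cannot derive an automatic young/old age threshold")
    return best


def classify_duplication_ages(
    trees: Sequence[GeneTree], threshold: float | str = "auto"
) -> dict[str, dict[int, str]]:
    """Classify each duplication node as ``"young"`` (age <= threshold,
    boundary inclusive) or ``"old"``.

    With ``threshold="auto"`` the threshold is the maximum speciation-node
    age over the whole tree set — the rationale being that speciation nodes
    are the only externally calibrated time points, so duplications older
    than all of them have unconstrained ages.
    Returns ``{tree_id: {node_id: "young"|"old"}}``.
    """
    if threshold == "auto":
        threshold = max_speciation_age(trees)
    out: dict[str, dict[int, str]] = {}
    for tree in trees:
        metrics = node_metrics(tree)
        out[tree.tree_id] = {
            node.id: ("young" if metrics[node.id].age <= threshold else "old")
            for node in tree.internal_nodes
            if node.event is Event.DUPLICATION
        }
    return out


# ---------------------------------------------------------------------------
# label repair and filters
# ---------------------------------------------------------------------------

def relabel_duplicate_speciation_labels(
    tree: GeneTree, labels: dict[int, str] | None = None
) -> tuple[GeneTree, int]:
    """Re-tag nested same-clade speciation nodes as NA.

    When the same clade name is borne by two speciation nodes on one
    root-to-tip path, time calibration would force all intervening branches
    to zero length; every such node except the oldest (closest to the root)
    is re-tagged ``NA_EVENT``.  Same-label nodes on disjoint paths are left
    alone.  ``labels`` maps node id -> clade name and defaults to the clade
    names carried by the tree itself.  Returns ``(tree, n_edits)``;
    the tree is modified in place.
    """
    if labels is None:
        labels = {n.id: n.clade for n in tree.internal_nodes if n.clade}
    n_edits = 0
    for node in tree.internal_nodes:
        if node.event is not Event.SPECIATION:
            continue
        name = labels.get(node.id)
        if not name:
            continue
        anc = node.parent
        while anc is not None:
            if anc.event is Event.SPECIATION and labels.get(anc.id) == name:
                node.event = Event.NA_EVENT
                n_edits += 1
                break
            anc = anc.parent
    return tree, n_edits


def prune_to_trait_tips(tree: GeneTree, traits: TraitTable) -> GeneTree | None:
    """Drop tips without trait data, collapsing unary nodes.

    Branch lengths of collapsed chains are summed, so patristic distances
    among the retained tips are preserved exactly.  Event tags of collapsed
    nodes are dropped (their count is recorded as ``tree.n_dropped_events``).
    Returns a new tree, or ``None`` if fewer than 2 tips remain.
    """
    dropped_events = 0

    def rec(node: Node) -> Node | None:
        nonlocal dropped_events
        if node.is_tip:
            if node.label in traits:
                return Node(length=node.length, label=node.label)
            return None
        kept = [c2 for c in node.children if (c2 := rec(c)) is not None]
        if not kept:
            if node.event is not None:
                dropped_events += 1
            return None
        if len(kept) == 1:
            # unary: splice out, summing branch lengths
            child = kept[0]
            if node.event is not None:
                dropped_events += 1
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        new = Node(length=node.length, event=node.event, clade=node.clade)
        for c in kept:
            new.add_child(c)
        return new

    new_root = rec(tree.root)
    if new_root is None or new_root.is_tip:
        return None
    new_root.length = None  # root carries no branch
    pruned = GeneTree(new_root, tree_id=tree.tree_id,
                      ultrametric=tree.ultrametric_expected)
    pruned.n_dropped_events = dropped_events
    return pruned


def filter_trees(
    trees: Sequence[GeneTree],
    traits: "TraitTable | dict[str, TraitTable]",
    min_trait_tips: int = 4,
    require_speciation: bool = True,
    require_duplication: bool = True,
    drop_negative_branches: bool = True,
) -> tuple[list[GeneTree], pd.DataFrame]:
    """Apply the study's tree-level inclusion rules.

    Rules, in order (a tree is reported with the first rule it violates):
    negative branch lengths; fewer than ``min_trait_tips`` tips with trait
    data; no speciation node; no duplication node.  Kept trees are pruned to
    tips with trait data.  Returns ``(kept, report)`` where ``report`` has
    columns ``tree_id, rule, detail``.
    """
    kept: list[GeneTree] = []
    rows: list[tuple[str, str, str]] = []
    for tree in trees:
        tr = traits[tree.tree_id] if isinstance(traits, dict) else traits
        if drop_negative_branches and tree.has_negative_branches():
            rows.append((tree.tree_id, "negative_branch_length", ""))
            continue
        n_with = sum(1 for t in tree.tips if t.label in tr)
        if n_with < min_trait_tips:
            rows.append((tree.tree_id, "min_trait_tips",
                         f"{n_with} < {min_trait_tips}"))
            continue
        pruned = prune_to_trait_tips(tree, tr)
        if pruned is None or pruned.n_tips < min_trait_tips:
            rows.append((tree.tree_id, "min_trait_tips", "after pruning"))
            continue
        events = [n.event for n in pruned.internal_nodes]
        if require_speciation and Event.SPECIATION not in events:
            rows.append((tree.tree_id, "no_speciation", "pure duplication/NA"))
            continue
        if require_duplication and Event.DUPLICATION not in events:
            rows.append((tree.tree_id, "no_duplication", "pure speciation/NA"))
            continue
        kept.append(pruned)
    report = pd.DataFrame(rows, columns=["tree_id", "rule", "detail"])
    return kept, report
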