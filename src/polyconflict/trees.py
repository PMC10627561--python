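"""Tree data model, Newick I/O, and bipartition/LCA/clade-frequency primitives.

Species trees carry branch lengths in coalescent units; gene trees carry
substitutions/site (or coalescent units when simulated).  Newick parsing is
delegated to dendropy; algorithms operate on a lightweight ``Node`` structure
so the simulators and reconciliation code can build and traverse trees cheaply.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping

import dendropy


class NewickParseError(ValueError):
    """Malformed Newick input."""


class DuplicateLabelError(ValueError):
    """Tip labels must be unique within a tree."""


class TipSetMismatchError(ValueError):
    """Operation requires trees on the same tip set."""


class Node:
    """A node in a rooted tree representation.

    ``length`` is the length of the branch subtending this node (``None`` at
    the root or when absent in the source Newick).
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """A (rooted or unrooted) tree with uniquely labeled tips.

    An unrooted tree is stored with an arbitrary root; ``rooted`` records
    whether the root placement is meaningful.
    """

    def __init__(self, root: Node, rooted: bool = True, validate: bool = True):
        self.root = root
        self.rooted = rooted
        if validate:
            self.validate()

    # -- construction / validation ------------------------------------------

    def validate(self) -> None:
        labels = [n.label for n in self.root.leaves()]
        if any(lab is None for lab in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateLabelError(f"duplicate tip labels: {dups}")
        for node in self.root.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Tree(rec(self.root), rooted=self.rooted, validate=False)

    # -- basic queries -------------------------------------------------------

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.root.leaves())

    def tips(self) -> list[Node]:
        return self.root.leaves()

    def n_tips(self) -> int:
        return len(self.root.leaves())

    def find_tip(self, label: str) -> Node:
        for n in self.root.leaves():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.root.preorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    # -- structure edits -----------------------------------------------------

    def suppress_unifurcations(self) -> None:
        """Collapse nodes with exactly one child, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.root.preorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    if node.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        parent.children[idx] = child
                        child.parent = parent
                    changed = True
                    break

    def restricted_to(self, labels: Iterable[str]) -> "Tree":
        """Copy of the tree pruned to ``labels`` (unifurcations suppressed)."""
        keep = set(labels)
        tree = self.copy()

        def prune(n: Node) -> Node | None:
            if n.is_leaf:
                return n if n.label in keep else None
            kept = [c for c in (prune(c) for c in n.children) if c is not None]
            if not kept:
                return None
            n.children = []
            for c in kept:
                n.add_child(c)
            return n

        root = prune(tree.root)
        if root is None:
            raise ValueError("restriction removed every tip")
        root.parent = None
        out = Tree(root, rooted=self.rooted, validate=False)
        out.suppress_unifurcations()
        return out

    # -- clades & bipartitions ----------------------------------------------

    def clade_sets(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Rooted clades as frozensets of tip labels.

        With ``nontrivial`` singleton clades and the full tip set are excluded.
        """
        all_tips = self.tip_labels
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            if not nontrivial or 1 < len(s) < len(all_tips):
                out.add(s)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, canonicalized to the side not
        containing the lexicographically smallest tip label."""
        all_tips = self.tip_labels
        if len(all_tips) < 4:
            return set()
        anchor = min(all_tips)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
                continue
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            side = all_tips - s if anchor in s else s
            if 1 < len(side) < len(all_tips) - 1:
                out.add(side)
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree(n_tips={self.n_tips()}, rooted={self.rooted})"


# -- Newick I/O ---------------------------------------------------------------


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, rooted: bool | None = None) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Internal node labels are kept as strings (support values etc.).  When
    ``rooted`` is None the tree is treated as rooted iff the root is a
    bifurcation or the string carries a ``[&R]`` hint.
    """
    if not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "duplicate" in str(exc).lower():
            raise DuplicateLabelError(str(exc)) from exc
        col = getattr(exc, "col_num", None)
        where = f" (near character {col})" if col is not None else ""
        raise NewickParseError(f"malformed Newick{where}: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    if rooted is None:
        if dtree.is_rooted:
            rooted = True
        else:
            rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)


def parse_newick_list(text: str, rooted: bool | None = None) -> list[Tree]:
    """Parse a multi-tree Newick document (one tree per ';')."""
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    return [parse_newick(c + ";", rooted=rooted) for c in chunks]


def read_trees(path: str, rooted: bool | None = None) -> list[Tree]:
    with open(path) as fh:
        return parse_newick_list(fh.read(), rooted=rooted)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, precision: int = 10) -> str:
    """Serialize to Newick; branch lengths to ``precision`` significant digits."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _quote_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _quote_label(str(node.label))
        if node.length is not None:
            s += f":{node.length:.{precision}g}"
        return s

    return fmt(tree.root) + ";"


def write_trees(trees: Iterable[Tree], path: str, precision: int = 10) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, precision=precision) + "\n")


# -- TaxonMap -----------------------------------------------------------------


@dataclass
class TaxonMap:
    """Many-to-one gene-copy label -> species label mapping."""

    mapping: dict[str, str] = field(default_factory=dict)

    def species_of(self, copy_label: str) -> str:
        try:
            return self.mapping[copy_label]
        except KeyError:
            # fall back to the species@k naming convention
            if "@" in copy_label:
                return copy_label.rsplit("@", 1)[0]
            raise

    def species(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    @classmethod
    def identity(cls, labels: Iterable[str]) -> "TaxonMap":
        return cls({lab: lab for lab in labels})

    @classmethod
    def from_copy_labels(cls, labels: Iterable[str]) -> "TaxonMap":
        """Build a map from ``species@k`` copy labels."""
        return cls({lab: lab.rsplit("@", 1)[0] if "@" in lab else lab for lab in labels})

    @classmethod
    def from_tsv(cls, path: str) -> "TaxonMap":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                copy_label, species = line.split("\t")[:2]
                if copy_label in mapping:
                    raise ValueError(f"gene copy {copy_label!r} mapped twice")
                mapping[copy_label] = species
        return cls(mapping)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for copy_label, species in sorted(self.mapping.items()):
                fh.write(f"{copy_label}\t{species}\n")

    def validate_against(self, gene_tips: Iterable[str], species_tips: Iterable[str]) -> None:
        species_set = set(species_tips)
        for tip in gene_tips:
            sp = self.species_of(tip)
            if sp not in species_set:
                raise ValueError(f"gene copy {tip!r} maps to unknown species {sp!r}")


@dataclass
class GeneTreeSet:
    """A collection of (possibly multi-copy) gene trees plus a taxon map."""

    trees: list[Tree]
    taxon_map: TaxonMap | None = None

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)


# -- comparisons --------------------------------------------------------------


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unrooted Robinson-Foulds distance (bipartition symmetric difference)."""
    if t1.tip_labels != t2.tip_labels:
        raise TipSetMismatchError(
            f"tip sets differ: {sorted(t1.tip_labels ^ t2.tip_labels)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def lca(tree: Tree, tips: Iterable[str]) -> Node:
    """Most recent common ancestor of ``tips`` in a rooted tree."""
    labels = set(tips)
    if not labels:
        raise ValueError("tips must be non-empty")
    unknown = labels - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"unknown tips: {sorted(unknown)}")
    below: dict[int, int] = {}
    target = len(labels)
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = 1 if node.label in labels else 0
        else:
            below[id(node)] = sum(below[id(c)] for c in node.children)
        if below[id(node)] == target:
            # postorder: the first node covering all targets is the LCA
            return node
    raise AssertionError("unreachable: root covers all tips")


def clade_frequencies(
    reference: Tree,
    collection: list[Tree],
    rooted: bool | None = None,
) -> dict[frozenset[str], float]:
    """Frequency of each non-trivial reference clade among ``collection``.

    Trees missing some reference tips are restricted to the shared tip set;
    a reference clade reduced to <2 tips (or a non-proper subset) for a given
    tree is skipped for that tree.  Matching is on rooted clades when both the
    reference and the collection are rooted, on unrooted bipartitions
    otherwise.
    """
    if not collection:
        raise ValueError("empty tree collection")
    if rooted is None:
        rooted = reference.rooted and all(t.rooted for t in collection)
    ref_tips = reference.tip_labels
    ref_clades = (
        sorted(reference.clade_sets(), key=lambda s: (len(s), sorted(s)))
        if rooted
        else sorted(reference.bipartitions(), key=lambda s: (len(s), sorted(s)))
    )
    hits = {c: 0 for c in ref_clades}
    evals = {c: 0 for c in ref_clades}
    for tree in collection:
        shared = ref_tips & tree.tip_labels
        t = tree if tree.tip_labels == ref_tips else tree.restricted_to(shared)
        tree_sets = t.clade_sets() if rooted else t.bipartitions()
        anchor = min(shared) if shared else None
        for clade in ref_clades:
            reduced = frozenset(clade & shared)
            if len(reduced) < 2 or len(shared - reduced) < 1:
                continue
            if rooted:
                evals[clade] += 1
                if reduced in tree_sets:
                    hits[clade] += 1
            else:
                if len(shared - reduced) < 2:
                    continue
                evals[clade] += 1
                side = frozenset(shared - reduced) if anchor in reduced else reduced
                if side in tree_sets:
                    hits[clade] += 1
    return {c: (hits[c] / evals[c]) if evals[c] else float("nan") for c in ref_clades}
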