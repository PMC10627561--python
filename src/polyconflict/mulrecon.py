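"""MUL-tree construction, reconciliation and allopolyploidy hypothesis search.

A MUL (multilabeled) tree represents a polyploidy hypothesis: the putative
polyploid clade H1 appears twice in the species tree, in situ and grafted at
a second placement H2.  Gene trees are reconciled against the MUL tree with
LCA duplication-loss counting, minimizing over the assignment of each H1-
species gene copy to one of the two MUL copies.  Summed over gene trees, a
lower reconciliation score for a MUL tree than for the singly-labeled species
tree supports allopolyploidy (H2 away from H1) or autopolyploidy (H2 on H1's
own branch); the reverse supports no WGD at H1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dupmap import _SpeciesIndex, lca_reconcile
from .trees import GeneTreeSet, Node, TaxonMap, Tree


@dataclass
class MULTree:
    """Species tree with the H1 clade appearing twice (tips repeat labels)."""

    tree: Tree
    h1: frozenset[str]
    h2: frozenset[str]
    first_copy: dict[str, Node] = field(default_factory=dict)
    second_copy: dict[str, Node] = field(default_factory=dict)


def _clade_node(tree: Tree, clade: frozenset[str] | str) -> Node:
    target = frozenset([clade]) if isinstance(clade, str) else frozenset(clade)
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        below[id(node)] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(below[id(c)] for c in node.children))
        )
        if below[id(node)] == target:
            return node
    raise KeyError(f"no node subtends clade {sorted(target)}")


def build_mul_tree(
    species: Tree, h1: frozenset[str] | str, h2: frozenset[str] | str
) -> MULTree:
    """Graft a second copy of the H1 clade onto the edge above the H2 clade.

    ``h1`` and ``h2`` are identified by the tip sets of the clades their
    branches subtend.  ``h2`` equal to ``h1`` places the second copy on H1's
    own branch (the autopolyploidy hypothesis); ``h2`` strictly inside H1 is
    invalid.
    """
    h1 = frozenset([h1]) if isinstance(h1, str) else frozenset(h1)
    h2 = frozenset([h2]) if isinstance(h2, str) else frozenset(h2)
    if h1 == species.tip_labels:
        raise ValueError("H1 cannot be the whole tree")
    work = species.copy()
    h1_node = _clade_node(work, h1)
    h2_node = _clade_node(work, h2)
    if h2 != h1 and h2 < h1:
        raise ValueError("H2 must not lie inside H1")
    if h2_node.parent is None:
        raise ValueError("H2 cannot be the root edge")
    # deep-copy the H1 subtree
    def rec(n: Node) -> Node:
        m = Node(n.label, n.length)
        for c in n.children:
            m.add_child(rec(c))
        return m

    graft = rec(h1_node)
    parent = h2_node.parent
    join = Node(length=(h2_node.length or 0.0) / 2.0 if h2_node.length is not None else None)
    idx = parent.children.index(h2_node)
    parent.children[idx] = join
    join.parent = parent
    if h2_node.length is not None:
        h2_node.length = h2_node.length / 2.0
    join.children = []
    join.add_child(h2_node)
    graft.length = h2_node.length
    join.add_child(graft)
    mul = MULTree(Tree(work.root, rooted=True, validate=False), h1, h2)
    graft_leaves = set(map(id, graft.leaves()))
    # first copy: every species' in-situ leaf; second copy: the grafted H1 leaves
    mul.first_copy = {
        leaf.label: leaf
        for leaf in mul.tree.tips()
        if id(leaf) not in graft_leaves
    }
    mul.second_copy = {leaf.label: leaf for leaf in graft.leaves()}
    return mul


# -- reconciliation with ambiguous tips --------------------------------------------


def _mul_index(mul: MULTree) -> _SpeciesIndex:
    # _SpeciesIndex builds clades/depths; duplicate labels are fine because
    # nodes are keyed by identity (leaf_of keeps the first copy only).
    return _SpeciesIndex(mul.tree)


def _score_assignment(
    gene: Tree,
    index: _SpeciesIndex,
    leaf_assign: dict[int, Node],
) -> tuple[int, int]:
    """(duplications, losses) of an LCA reconciliation with fixed tip mapping."""
    mapping: dict[int, Node] = {}
    dups = losses = 0
    for node in gene.postorder():
        if node.is_leaf:
            mapping[id(node)] = leaf_assign[id(node)]
            continue
        it = iter(node.children)
        m = mapping[id(next(it))]
        for c in it:
            m = index.lca(m, mapping[id(c)])
        mapping[id(node)] = m
        is_dup = any(mapping[id(c)] is m for c in node.children)
        if is_dup:
            dups += 1
        for c in node.children:
            gap = index.depth[id(mapping[id(c)])] - index.depth[id(m)]
            losses += gap if is_dup else max(gap - 1, 0)
    return dups, losses


def mul_reconcile(
    gene: Tree,
    mul: MULTree,
    taxon_map: TaxonMap,
    cap: int = 12,
    n_restarts: int = 5,
    seed: int = 0,
    index: _SpeciesIndex | None = None,
) -> tuple[int, int, int]:
    """Minimal (cost, duplications, losses) over ambiguous-tip assignments.

    Gene copies of H1 species may sit in either MUL copy; the assignment is
    enumerated exhaustively when there are <= ``cap`` ambiguous tips (exact),
    otherwise refined greedily by single-tip flips from random starts.
    """
    index = index or _mul_index(mul)
    fixed: dict[int, Node] = {}
    ambiguous: list[tuple[int, Node, Node]] = []
    for tip in gene.tips():
        sp = taxon_map.species_of(tip.label)
        if sp in mul.first_copy and sp in mul.second_copy:
            ambiguous.append((id(tip), mul.first_copy[sp], mul.second_copy[sp]))
        elif sp in mul.first_copy:
            fixed[id(tip)] = mul.first_copy[sp]
        else:
            raise KeyError(f"gene copy {tip.label!r} maps to unknown species {sp!r}")

    def score(bits: tuple[int, ...]) -> tuple[int, int, int]:
        assign = dict(fixed)
        for bit, (tid, a, b) in zip(bits, ambiguous):
            assign[tid] = b if bit else a
        d, l = _score_assignment(gene, index, assign)
        return d + l, d, l

    k = len(ambiguous)
    if k == 0:
        return score(())
    if k <= cap:
        return min(score(bits) for bits in itertools.product((0, 1), repeat=k))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        bits = list(rng.integers(0, 2, size=k))
        cur = score(tuple(bits))
        improved = True
        while improved:
            improved = False
            for i in range(k):
                bits[i] ^= 1
                cand = score(tuple(bits))
                if cand < cur:
                    cur = cand
                    improved = True
                else:
                    bits[i] ^= 1
        if best is None or cur < best:
            best = cur
    return best


# -- hypothesis search ---------------------------------------------------------------


@dataclass
class ReconScore:
    h1: frozenset[str] | None  # None = singly-labeled species tree
    h2: frozenset[str] | None
    total: int
    duplications: int
    losses: int
    n_trees: int
    n_trees_best: int = 0

    @property
    def hypothesis_id(self) -> str:
        if self.h1 is None:
            return "singly-labeled"
        return f"H1={'+'.join(sorted(self.h1))}|H2={'+'.join(sorted(self.h2))}"


def candidate_h2_edges(species: Tree, h1: frozenset[str]) -> list[frozenset[str]]:
    """All edges (as subtended clades) usable as H2 for a given H1."""
    out = []
    below: dict[int, frozenset[str]] = {}
    for node in species.postorder():
        below[id(node)] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(below[id(c)] for c in node.children))
        )
        clade = below[id(node)]
        if node.parent is None:
            continue
        if clade < h1:
            continue  # inside H1
        out.append(clade)
    return out


def grampa_search(
    genes: GeneTreeSet,
    species: Tree,
    h1_candidates: list[frozenset[str]],
    h2_candidates: list[frozenset[str]] | str = "all",
    cap: int = 12,
    taxon_map: TaxonMap | None = None,
) -> list[ReconScore]:
    """Score every (H1, H2) MUL-tree hypothesis plus the singly-labeled tree.

    Scores are duplications+losses summed over gene trees; results are ranked
    ascending (ties: fewer duplications, then hypothesis id).  ``n_trees_best``
    counts gene trees for which the hypothesis reconciles strictly better than
    the singly-labeled species tree.
    """
    if not genes.trees:
        raise ValueError("empty gene-tree set")
    if not h1_candidates:
        raise ValueError("need at least one H1 candidate")
    tmap = taxon_map or genes.taxon_map or TaxonMap.from_copy_labels(
        lab for t in genes for lab in (tip.label for tip in t.tips())
    )
    base_d = base_l = 0
    base_scores = []
    for gene in genes:
        rec = lca_reconcile(gene, species, tmap)
        base_d += rec.n_duplications
        base_l += rec.losses
        base_scores.append(rec.cost)
    results = [
        ReconScore(None, None, base_d + base_l, base_d, base_l, len(genes.trees))
    ]
    for h1 in h1_candidates:
        h1 = frozenset(h1)
        edges = (
            candidate_h2_edges(species, h1)
            if h2_candidates == "all"
            else [frozenset(e) for e in h2_candidates]
        )
        for h2 in edges:
            try:
                mul = build_mul_tree(species, h1, h2)
            except (ValueError, KeyError):
                continue
            index = _mul_index(mul)
            tot_d = tot_l = n_best = 0
            for gene, base in zip(genes, base_scores):
                cost, d, l = mul_reconcile(gene, mul, tmap, cap=cap, index=index)
                tot_d += d
                tot_l += l
                n_best += cost < base
            results.append(
                ReconScore(h1, h2, tot_d + tot_l, tot_d, tot_l, len(genes.trees), n_best)
            )
    results.sort(key=lambda r: (r.total, r.duplications, r.hypothesis_id))
    return results
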