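"""LCA duplication-loss reconciliation and ladder-based duplication mapping.

Gene duplications are located on the species tree by the standard LCA
mapping; a MAPS-style analysis then scores, at each node of a nested ladder
of clades, the percentage of gene subtrees exhibiting a duplication shared by
the node's descendants, and compares it against pooled null (no-WGD) and
positive (WGD) simulations with one-sided Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .trees import GeneTreeSet, Node, TaxonMap, Tree


# -- species-tree indexing ------------------------------------------------------


class _SpeciesIndex:
    """Clades, depths, parents and a pairwise LCA table for a species tree."""

    def __init__(self, species: Tree):
        self.tree = species
        self.clade: dict[int, frozenset[str]] = {}
        self.depth: dict[int, int] = {}
        self.leaf_of: dict[str, Node] = {}
        for node in species.postorder():
            if node.is_leaf:
                self.clade[id(node)] = frozenset([node.label])
                self.leaf_of[node.label] = node
            else:
                self.clade[id(node)] = frozenset().union(
                    *(self.clade[id(c)] for c in node.children)
                )
        for node in species.preorder():
            self.depth[id(node)] = 0 if node.parent is None else self.depth[id(node.parent)] + 1

    def lca(self, a: Node, b: Node) -> Node:
        da, db = self.depth[id(a)], self.depth[id(b)]
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def node_of_clade(self, clade: frozenset[str] | str) -> Node:
        target = frozenset([clade]) if isinstance(clade, str) else frozenset(clade)
        for node in self.tree.postorder():
            if self.clade[id(node)] == target:
                return node
        raise KeyError(f"no species node subtends {sorted(target)}")


def _lca_map(
    gene: Tree, index: _SpeciesIndex, leaf_assign: dict[int, Node]
) -> dict[int, Node]:
    """Map every gene node to a species node (tips via ``leaf_assign``)."""
    mapping: dict[int, Node] = {}
    for node in gene.postorder():
        if node.is_leaf:
            mapping[id(node)] = leaf_assign[id(node)]
        else:
            it = iter(node.children)
            m = mapping[id(next(it))]
            for c in it:
                m = index.lca(m, mapping[id(c)])
            mapping[id(node)] = m
    return mapping


def _events(
    gene: Tree, index: _SpeciesIndex, mapping: dict[int, Node]
) -> tuple[dict[int, int], int]:
    """Duplication nodes (keyed by species node id) and total losses."""
    dups: dict[int, int] = {}
    losses = 0
    for node in gene.postorder():
        if node.is_leaf:
            continue
        m = mapping[id(node)]
        is_dup = any(mapping[id(c)] is m for c in node.children)
        if is_dup:
            dups[id(m)] = dups.get(id(m), 0) + 1
        for c in node.children:
            gap = index.depth[id(mapping[id(c)])] - index.depth[id(m)]
            losses += gap if is_dup else max(gap - 1, 0)
    return dups, losses


@dataclass
class Reconciliation:
    duplications: dict[frozenset[str], int]
    n_duplications: int
    losses: int
    cost: int


def lca_reconcile(gene: Tree, species: Tree, taxon_map: TaxonMap) -> Reconciliation:
    """Standard LCA duplication-loss reconciliation of a rooted gene tree.

    A gene node is a duplication iff its mapping equals a child's mapping;
    losses follow the usual depth-gap rule.  Duplication counts are keyed by
    the species-node clade.
    """
    index = _SpeciesIndex(species)
    leaf_assign = {}
    for tip in gene.tips():
        sp = taxon_map.species_of(tip.label)
        if sp not in index.leaf_of:
            raise KeyError(f"gene copy {tip.label!r} maps to unknown species {sp!r}")
        leaf_assign[id(tip)] = index.leaf_of[sp]
    mapping = _lca_map(gene, index, leaf_assign)
    dups, losses = _events(gene, index, mapping)
    by_clade = {index.clade[nid]: k for nid, k in dups.items()}
    n_dups = sum(dups.values())
    return Reconciliation(by_clade, n_dups, losses, n_dups + losses)


# -- ladders ----------------------------------------------------------------------


@dataclass
class LadderStep:
    node_clade: frozenset[str]   # clade of the species-tree node
    ingroup: frozenset[str]      # taxa accumulated tipward along the ladder
    new_group: frozenset[str]    # sister taxa added at this step


@dataclass
class Ladder:
    species: Tree                # species tree restricted to the ladder taxa
    anchor: str
    steps: list[LadderStep]

    @property
    def taxa(self) -> frozenset[str]:
        return self.species.tip_labels


def build_ladder(
    species: Tree, anchor: str, representatives: list[str] | None = None
) -> Ladder:
    """Nested ladder of clades from ``anchor`` to the root.

    ``representatives`` restricts the species tree to one (or a few) taxa per
    subtending clade before the walk, as ladder-based duplication mapping
    expects.
    """
    tree = species.restricted_to(representatives) if representatives else species.copy()
    tip = tree.find_tip(anchor)
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        below[id(node)] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(below[id(c)] for c in node.children))
        )
    steps = []
    node = tip
    ingroup = frozenset([anchor])
    while node.parent is not None:
        parent = node.parent
        new = frozenset().union(
            *(below[id(c)] for c in parent.children if c is not node)
        )
        steps.append(LadderStep(below[id(parent)], ingroup, new))
        ingroup = ingroup | new
        node = parent
    return Ladder(tree, anchor, steps)


# -- MAPS-style analysis -----------------------------------------------------------


@dataclass
class NodeDupProfile:
    node_clade: frozenset[str]
    examined: int
    shared: int
    percentage: float
    p_null: float = float("nan")
    p_positive: float = float("nan")
    wgd_like: bool = False


def maps_analysis(
    genes: GeneTreeSet,
    ladder: Ladder,
    taxon_map: TaxonMap | None = None,
) -> list[NodeDupProfile]:
    """Per-ladder-node shared-duplication percentages over gene subtrees.

    For each gene tree (restricted to the ladder taxa), the maximal subtrees
    LCA-mapping to a ladder node are examined, provided they contain >= 1 copy
    of every ladder taxon covered by that node and contain no duplication
    mapping elsewhere (topological concordance).  A subtree supports a shared
    duplication at the node iff it has a duplication node mapping there whose
    two children each retain >= 1 taxon of the node's ingroup.
    """
    tmap = taxon_map or genes.taxon_map
    if tmap is None:
        raise ValueError("a TaxonMap is required")
    index = _SpeciesIndex(ladder.species)
    ladder_taxa = ladder.taxa
    node_ids = [id(index.node_of_clade(s.node_clade)) for s in ladder.steps]
    examined = {nid: 0 for nid in node_ids}
    shared = {nid: 0 for nid in node_ids}
    covered = {nid: step.ingroup | step.new_group for nid, step in zip(node_ids, ladder.steps)}
    ingroups = {nid: step.ingroup for nid, step in zip(node_ids, ladder.steps)}

    for gene in genes:
        keep = [t.label for t in gene.tips() if tmap.species_of(t.label) in ladder_taxa]
        if len(keep) < 2:
            continue
        sub = gene.restricted_to(keep)
        leaf_assign = {
            id(t): index.leaf_of[tmap.species_of(t.label)] for t in sub.tips()
        }
        mapping = _lca_map(sub, index, leaf_assign)
        species_below: dict[int, set[str]] = {}
        for node in sub.postorder():
            if node.is_leaf:
                species_below[id(node)] = {tmap.species_of(node.label)}
            else:
                species_below[id(node)] = set().union(
                    *(species_below[id(c)] for c in node.children)
                )
        for v in sub.preorder():
            if v.is_leaf:
                continue
            m = mapping[id(v)]
            if id(m) not in examined:
                continue
            if v.parent is not None and mapping[id(v.parent)] is m:
                continue  # not maximal
            if not covered[id(m)] <= species_below[id(v)]:
                continue
            internal = [w for w in v.postorder() if not w.is_leaf]
            dups_here, foreign_dup = [], False
            for w in internal:
                if any(mapping[id(c)] is mapping[id(w)] for c in w.children):
                    if mapping[id(w)] is m:
                        dups_here.append(w)
                    else:
                        foreign_dup = True
            if foreign_dup:
                continue
            examined[id(m)] += 1
            ingroup = ingroups[id(m)]
            for w in dups_here:
                if len(w.children) >= 2 and all(
                    species_below[id(c)] & ingroup for c in w.children[:2]
                ):
                    shared[id(m)] += 1
                    break
    out = []
    for nid, step in zip(node_ids, ladder.steps):
        ex, sh = examined[nid], shared[nid]
        out.append(
            NodeDupProfile(step.node_clade, ex, sh, (sh / ex) if ex else float("nan"))
        )
    return out


def maps_significance(
    observed: list[NodeDupProfile],
    null_profiles: list[list[NodeDupProfile]],
    positive_profiles: list[list[NodeDupProfile]],
    alpha: float = 0.05,
) -> list[NodeDupProfile]:
    """Flag nodes whose shared-duplication rate exceeds the null and is not
    significantly below the positive (WGD) simulations.

    Simulation replicates are pooled per node; comparisons are one-sided
    Fisher exact tests.  A node can only be flagged WGD-like where the
    positive model itself predicts an excess over the null (the consistency
    comparison is uninformative at nodes the simulated WGD does not affect).
    Returns new profiles with p-values and flags set.
    """

    def pooled(profiles: list[list[NodeDupProfile]], clade: frozenset[str]) -> tuple[int, int]:
        ex = sh = 0
        for rep in profiles:
            for p in rep:
                if p.node_clade == clade:
                    ex += p.examined
                    sh += p.shared
        return sh, ex

    out = []
    for obs in observed:
        if obs.examined == 0:
            out.append(obs)
            continue
        null_sh, null_ex = pooled(null_profiles, obs.node_clade)
        pos_sh, pos_ex = pooled(positive_profiles, obs.node_clade)
        table_null = [
            [obs.shared, obs.examined - obs.shared],
            [null_sh, max(null_ex - null_sh, 0)],
        ]
        p_null = (
            stats.fisher_exact(table_null, alternative="greater")[1]
            if null_ex
            else float("nan")
        )
        table_pos = [
            [obs.shared, obs.examined - obs.shared],
            [pos_sh, max(pos_ex - pos_sh, 0)],
        ]
        p_pos = (
            stats.fisher_exact(table_pos, alternative="less")[1]
            if pos_ex
            else float("nan")
        )
        pos_informative = bool(pos_ex and null_ex) and (
            stats.fisher_exact(
                [[pos_sh, max(pos_ex - pos_sh, 0)], [null_sh, max(null_ex - null_sh, 0)]],
                alternative="greater",
            )[1]
            < alpha
        )
        flag = (
            pos_informative
            and (p_null == p_null and p_null < alpha)
            and not (p_pos == p_pos and p_pos < alpha)
        )
        out.append(
            NodeDupProfile(
                obs.node_clade, obs.examined, obs.shared, obs.percentage,
                p_null, p_pos, flag,
            )
        )
    return out
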