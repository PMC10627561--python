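"""Orthogroup selection, long-branch pruning, and rooted-tree (RT) orthology.

These are the gene-tree curation filters applied before any discordance or
duplication analysis: copy-number criteria on orthogroups, removal of
implausibly long terminal/internal branches from homolog trees, and extraction
of maximal single-copy ortholog subtrees by pruning at duplication nodes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .trees import Node, TaxonMap, Tree


@dataclass(frozen=True)
class OrthogroupStats:
    """Per-species gene-copy counts for one orthogroup."""

    og_id: str
    counts: dict[str, int]  # species -> copy count (0 allowed)

    @property
    def n_present(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


def select_orthogroups(
    stats: list[OrthogroupStats],
    min_presence: int | None = None,
    max_mean: float = 5.0,
    max_median: float = 2.0,
    include_absent: bool = False,
) -> list[str]:
    """Retain orthogroups meeting the copy-number criteria.

    Defaults: present in every species (``min_presence=None`` means all
    species seen across ``stats``), mean copy number <= 5, median <= 2.
    Mean/median are computed over species with >= 1 copy unless
    ``include_absent``.
    """
    if not stats:
        return []
    all_species = set()
    for st in stats:
        all_species.update(st.counts)
    need = len(all_species) if min_presence is None else min_presence
    retained = []
    for st in stats:
        if st.n_present < need:
            continue
        vals = [c for c in st.counts.values() if include_absent or c > 0]
        if not vals:
            continue
        if statistics.fmean(vals) > max_mean:
            continue
        if statistics.median(vals) > max_median:
            continue
        retained.append(st.og_id)
    return retained


# -- long-branch pruning --------------------------------------------------------


@dataclass
class CurationResult:
    """Outcome of pruning: the curated tree (or None if discarded) plus a log."""

    tree: Tree | None
    discarded: bool
    log: list[str] = field(default_factory=list)


def _sister_terminal_max(tip: Node) -> float | None:
    """Maximum terminal branch length within the tip's sister clade(s)."""
    parent = tip.parent
    if parent is None:
        return None
    best = None
    for sib in parent.children:
        if sib is tip:
            continue
        for leaf in sib.leaves():
            if leaf.length is not None:
                best = leaf.length if best is None else max(best, leaf.length)
    return best


def prune_long_branches(
    tree: Tree,
    tip_cutoff: float = 0.2,
    ratio: float = 10.0,
    abs_cutoff: float = 0.5,
    min_tips: int = 4,
) -> CurationResult:
    """Iteratively remove suspiciously long branches (substitutions/site).

    Two rules, iterated to a fixed point: (a) cut any branch (terminal or
    internal) longer than ``abs_cutoff``, keeping the component with more
    tips; (b) prune any tip whose branch exceeds ``tip_cutoff`` AND
    ``ratio`` x the longest terminal branch in its sister clade.  A tree
    reduced below ``min_tips`` is flagged as discarded rather than raising.
    """
    work = tree.copy()
    log: list[str] = []

    def drop_node(node: Node) -> None:
        parent = node.parent
        parent.children.remove(node)
        node.parent = None

    changed = True
    while changed:
        changed = False
        if work.n_tips() < min_tips:
            log.append(f"discarded: fewer than {min_tips} tips remain")
            return CurationResult(None, True, log)
        # rule (a): absolute cutoff, longest offender first
        offenders = [
            n
            for n in work.root.preorder()
            if n.parent is not None and n.length is not None and n.length > abs_cutoff
        ]
        if offenders:
            node = max(offenders, key=lambda n: n.length)
            below = len(node.leaves())
            above = work.n_tips() - below
            if below > above or (below == above and not node.is_leaf):
                # keep the subtree below the cut branch
                log.append(
                    f"abs_cutoff: branch {node.length:.4g} cut, kept {below}-tip side"
                )
                node.parent = None
                node.length = None
                work = Tree(node, rooted=work.rooted, validate=False)
                if node.is_leaf:
                    log.append("discarded: single tip remains")
                    return CurationResult(None, True, log)
            else:
                log.append(
                    f"abs_cutoff: branch {node.length:.4g} cut, kept {above}-tip side"
                )
                drop_node(node)
            work.suppress_unifurcations()
            work.root.length = None
            changed = True
            continue
        # rule (b): tip-vs-sister ratio
        for tip in work.tips():
            if tip.length is None or tip.length <= tip_cutoff or tip.parent is None:
                continue
            sister_max = _sister_terminal_max(tip)
            if sister_max is not None and tip.length > ratio * sister_max:
                log.append(
                    f"tip_ratio: tip {tip.label!r} ({tip.length:.4g}) pruned "
                    f"(sister max {sister_max if sister_max is not None else 'n/a'})"
                )
                drop_node(tip)
                work.suppress_unifurcations()
                changed = True
                break
        if work.n_tips() < min_tips:
            log.append(f"discarded: fewer than {min_tips} tips remain")
            return CurationResult(None, True, log)
    return CurationResult(work, False, log)


# -- RT ortholog extraction -------------------------------------------------------


def _species_below(node: Node, taxon_map: TaxonMap) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for n in node.postorder():
        if n.is_leaf:
            out[id(n)] = frozenset([taxon_map.species_of(n.label)])
        else:
            out[id(n)] = frozenset().union(*(out[id(c)] for c in n.children))
    return out


def _is_single_copy(node: Node, taxon_map: TaxonMap) -> bool:
    seen = set()
    for leaf in node.leaves():
        sp = taxon_map.species_of(leaf.label)
        if sp in seen:
            return False
        seen.add(sp)
    return True


def _reroot_on_outgroups(tree: Tree, out_tips: list[Node]) -> Tree:
    """Reroot so the outgroup copies' MRCA-side is one child of the root."""
    work = tree.copy()
    labels = {t.label for t in out_tips}
    anchor = next(n for n in work.tips() if n.label in labels)
    # walk rootward from the anchor: the reroot edge is above the maximal
    # all-outgroup clade containing the anchor (the anchor's own edge when the
    # outgroup copies are not monophyletic around it)
    target = anchor
    node = anchor
    while node.parent is not None:
        leaves = {l.label for l in node.leaves()}
        if not leaves <= labels:
            break
        target = node
        node = node.parent
    if target.parent is work.root and len(work.root.children) == 2:
        return work  # already rooted on that edge

    # reroot on the edge above `target`
    old_parent = target.parent
    new_root = Node()
    half = (target.length or 0.0) / 2.0
    # invert parent chain from old_parent up to the old root
    chain = []
    n = old_parent
    while n is not None:
        chain.append(n)
        n = n.parent
    old_parent.children.remove(target)
    for i in range(len(chain) - 1):
        child, par = chain[i], chain[i + 1]
        par.children.remove(child)
        child.add_child(par)
        par.length = child.length
    # collapse the old root if left unary
    target.length = half
    target.parent = None
    new_root.add_child(target)
    old_parent.length = half
    old_parent.parent = None
    new_root.add_child(old_parent)
    out = Tree(new_root, rooted=True, validate=False)
    out.suppress_unifurcations()
    return out


@dataclass
class RTResult:
    orthologs: list[Tree]
    skipped_reason: str | None = None


def extract_rt_orthologs(
    homolog_tree: Tree,
    taxon_map: TaxonMap,
    outgroups: set[str],
    min_taxa: int = 4,
) -> RTResult:
    """Rooted-tree orthology: root on outgroups, split at duplication nodes.

    Traversing rootward-to-tipward, any node whose child subtrees share >= 1
    species is a putative duplication: the child with more distinct species is
    kept (ties: more tips, then lexicographically smallest species set) and
    re-examined.  Maximal single-copy subtrees with >= ``min_taxa`` species
    are emitted (outgroup copies removed).
    """
    if homolog_tree.n_tips() < 3:
        return RTResult([], skipped_reason="fewer than three tips")
    out_tips = [
        t for t in homolog_tree.tips() if taxon_map.species_of(t.label) in outgroups
    ]
    if not out_tips:
        return RTResult([], skipped_reason="no outgroup copy present")
    rooted = _reroot_on_outgroups(homolog_tree, out_tips)
    ingroup_labels = [
        t.label for t in rooted.tips() if taxon_map.species_of(t.label) not in outgroups
    ]
    if len(ingroup_labels) < 2:
        return RTResult([], skipped_reason="fewer than two ingroup copies")
    try:
        ingroup = rooted.restricted_to(ingroup_labels)
    except ValueError:
        return RTResult([], skipped_reason="no ingroup copies after rooting")

    species_below = _species_below(ingroup.root, taxon_map)
    orthologs: list[Tree] = []

    def rank(child: Node) -> tuple:
        # more species, then more tips, then lexicographically smallest set
        return (
            -len(species_below[id(child)]),
            -len(child.leaves()),
            sorted(species_below[id(child)]),
        )

    queue = [ingroup.root]
    while queue:
        node = queue.pop()
        if _is_single_copy(node, taxon_map):
            if len(species_below[id(node)]) >= min_taxa:
                sub = Tree(_detach_copy(node), rooted=True, validate=False)
                orthologs.append(sub)
            continue
        if node.is_leaf:
            continue
        shared = False
        for i, a in enumerate(node.children):
            for b in node.children[i + 1 :]:
                if species_below[id(a)] & species_below[id(b)]:
                    shared = True
        if shared:
            best = min(node.children, key=rank)
            queue.append(best)
        else:
            queue.extend(node.children)
    return RTResult(orthologs)


def _detach_copy(node: Node) -> Node:
    def rec(n: Node) -> Node:
        m = Node(n.label, n.length)
        for c in n.children:
            m.add_child(rec(c))
        return m

    out = rec(node)
    out.length = None
    return out
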