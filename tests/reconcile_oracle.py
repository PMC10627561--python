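"""Brute-force duplication-loss reconciliation oracle for tests.

Exhaustively minimizes duplications + losses over every consistent mapping of
gene-tree internal nodes to species-tree nodes (each internal gene node may
map to any ancestor-or-equal of the LCA of its children's mappings), applying
the general event rules: a node is a speciation only when its two children map
strictly below it into distinct child subtrees.
"""

import itertools

from polyconflict.dupmap import _SpeciesIndex


def brute_force_min_cost(gene, species, taxon_map):
    index = _SpeciesIndex(species)
    internal = [n for n in gene.postorder() if not n.is_leaf]
    tip_map = {id(t): index.leaf_of[taxon_map.species_of(t.label)] for t in gene.tips()}

    def ancestors(node):
        out = [node]
        while node.parent is not None:
            node = node.parent
            out.append(node)
        return out

    base = dict(tip_map)
    for n in internal:
        it = iter(n.children)
        v = base[id(next(it))]
        for c in it:
            v = index.lca(v, base[id(c)])
        base[id(n)] = v

    choices = [ancestors(base[id(n)]) for n in internal]
    best = None
    for combo in itertools.product(*choices):
        m = dict(tip_map)
        m.update({id(n): s for n, s in zip(internal, combo)})
        ok = True
        cost = 0
        for n in internal:
            mn = m[id(n)]
            child_maps = [m[id(c)] for c in n.children]
            if any(mn not in ancestors(cm) for cm in child_maps):
                ok = False
                break
            sides = []
            for cm in child_maps:
                side = None
                for k in mn.children:
                    if k in ancestors(cm):
                        side = k
                sides.append(side)
            speciation = (
                len(n.children) == 2
                and all(s is not None for s in sides)
                and sides[0] is not sides[1]
            )
            if not speciation:
                cost += 1
            for cm in child_maps:
                gap = index.depth[id(cm)] - index.depth[id(mn)]
                cost += gap - 1 if speciation else gap
        if ok and (best is None or cost < best):
            best = cost
    return best
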