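"""Quartet concordance factors, MSC hypothesis tests, and per-edge scores.

A quartet count concordance factor (qcCF) is the triple (n1, n2, n3) of gene
trees displaying each of the three resolutions of a four-taxon set.  Under
the MSC the discordant resolutions are exchangeable, so qcCFs should follow a
multinomial (1-2mu, mu, mu) law with mu in [0, 1/3]; the T3 test fits the
concordant class freely (no species tree assumed) while the T1 test fixes it
from a known species tree.  Rejected quartets can be mapped back onto species
tree edges, and an internode-certainty-style score summarizes per-edge
concordance from quadripartition quartet frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .trees import GeneTreeSet, Tree


@dataclass(frozen=True)
class QuartetCounts:
    """Counts of the three resolutions of a sorted taxon quadruple.

    With labels sorted as x0<x1<x2<x3, the canonical resolution order is
    x0x1|x2x3, x0x2|x1x3, x0x3|x1x2.
    """

    quadruple: tuple[str, str, str, str]
    counts: tuple[int, int, int]

    @property
    def n(self) -> int:
        return sum(self.counts)


def _resolution_index(quadruple: tuple[str, ...], pair: frozenset[str]) -> int:
    """Canonical index of the resolution that groups ``pair`` together."""
    x0 = quadruple[0]
    if x0 not in pair:
        pair = frozenset(quadruple) - pair
    partner = next(iter(pair - {x0}))
    return quadruple.index(partner) - 1


def _tree_clades(tree: Tree) -> list[frozenset[str]]:
    out = []
    below: dict[int, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            out.append(s)
    return out


def induced_resolution(
    clades: list[frozenset[str]], quadruple: tuple[str, ...]
) -> int | None:
    """Resolution index displayed by a tree (via its clade list), or None."""
    q = frozenset(quadruple)
    for clade in clades:
        inter = clade & q
        if len(inter) == 2 and len(q - clade) == 2:
            return _resolution_index(quadruple, frozenset(inter))
    return None


def count_quartets(
    genes: GeneTreeSet | list[Tree],
    quadruples="all",
    seed: int = 0,
) -> list[QuartetCounts]:
    """qcCFs over the gene-tree collection.

    ``quadruples`` may be "all", an explicit list of 4-tuples, or an integer m
    (a random sample of m quadruples).  A gene tree contributes to a quadruple
    only when it contains all four taxa.
    """
    trees = list(genes.trees if isinstance(genes, GeneTreeSet) else genes)
    all_taxa = sorted(set().union(*(t.tip_labels for t in trees))) if trees else []
    if quadruples == "all":
        quads = [tuple(q) for q in itertools.combinations(all_taxa, 4)]
    elif isinstance(quadruples, int):
        rng = np.random.default_rng(seed)
        every = list(itertools.combinations(all_taxa, 4))
        m = min(quadruples, len(every))
        idx = rng.choice(len(every), size=m, replace=False)
        quads = [tuple(every[i]) for i in idx]
    else:
        quads = []
        for q in quadruples:
            if len(set(q)) != 4:
                raise ValueError(f"quadruple must have 4 distinct labels: {q}")
            quads.append(tuple(sorted(q)))
    cache = [( t.tip_labels, _tree_clades(t)) for t in trees]
    results = []
    for quad in quads:
        counts = [0, 0, 0]
        qset = set(quad)
        for tips, clades in cache:
            if not qset <= tips:
                continue
            r = induced_resolution(clades, quad)
            if r is not None:
                counts[r] += 1
        results.append(QuartetCounts(quad, tuple(counts)))
    return results


# -- T1 / T3 hypothesis tests -----------------------------------------------------


@dataclass
class QuartetTestResult:
    quadruple: tuple[str, ...]
    counts: tuple[int, int, int]
    mu_hat: float
    lrt: float
    p_value: float
    model: str
    alpha: float
    rejected: bool
    concordant_index: int


def _lrt_stat(counts: np.ndarray, conc_idx: np.ndarray | int | None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized LRT of the (1-2mu, mu, mu) null; counts shape (..., 3).

    ``conc_idx`` None fits the concordant class as the modal count (T3);
    otherwise it is fixed (T1).  Returns (lrt, mu_hat).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    n1 = counts.max(axis=-1) if conc_idx is None else counts[..., conc_idx]
    m = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.minimum(m / (2.0 * n), 1.0 / 3.0)
        full = (xlogy(counts, counts) - xlogy(counts, n[..., None])).sum(axis=-1)
        null = xlogy(n1, 1.0 - 2.0 * mu) + xlogy(m, mu)
    lrt = np.maximum(2.0 * (full - null), 0.0)
    return lrt, mu

def _test(
    counts: QuartetCounts,
    conc_idx: int | None,
    alpha: float,
    pvalue_method: str,
    B: int,
    seed: int,
    model: str,
) -> QuartetTestResult:
    c = np.asarray(counts.counts, dtype=float)
    n = int(c.sum())
    if n == 0:
        return QuartetTestResult(
            counts.quadruple, counts.counts, float("nan"), float("nan"),
            float("nan"), model, alpha, False, -1 if conc_idx is None else conc_idx,
        )
    lrt, mu = _lrt_stat(c, conc_idx)
    lrt, mu = float(lrt), float(mu)
    used_idx = int(np.argmax(c)) if conc_idx is None else conc_idx
    if pvalue_method == "chisq1":
        p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    elif pvalue_method == "bootstrap":
        probs = np.full(3, mu)
        probs[used_idx] = 1.0 - 2.0 * mu
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(n, probs, size=B)
        boot_lrt, _ = _lrt_stat(sims, conc_idx)
        p = float((1 + np.sum(boot_lrt >= lrt - 1e-12)) / (B + 1))
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    return QuartetTestResult(
        counts.quadruple, counts.counts, mu, lrt, p, model, alpha, p < alpha, used_idx
    )


def t3_test(
    counts: QuartetCounts,
    alpha: float = 0.01,
    pvalue_method: str = "bootstrap",
    B: int = 2000,
    seed: int = 0,
) -> QuartetTestResult:
    """MSC fit with no species-tree hypothesis: the modal count is concordant."""
    return _test(counts, None, alpha, pvalue_method, B, seed, "T3")


def t1_test(
    counts: QuartetCounts,
    species_resolution: int,
    alpha: float = 0.01,
    pvalue_method: str = "bootstrap",
    B: int = 2000,
    seed: int = 0,
) -> QuartetTestResult:
    """MSC fit with the concordant class fixed by a known species tree."""
    if species_resolution not in (0, 1, 2):
        raise ValueError("species_resolution must be 0, 1 or 2")
    return _test(counts, species_resolution, alpha, pvalue_method, B, seed, "T1")


def species_tree_resolution(species: Tree, quadruple: tuple[str, ...]) -> int:
    """Canonical resolution index the species tree displays for a quadruple."""
    quad = tuple(sorted(quadruple))
    r = induced_resolution(_tree_clades(species), quad)
    if r is None:
        raise ValueError(f"species tree does not resolve quadruple {quad}")
    return r


def simplex_coordinates(counts: QuartetCounts) -> tuple[float, float, float]:
    """Barycentric coordinates of a qcCF (p1, p2, p3)."""
    n = counts.n
    if n == 0:
        raise ValueError("cannot place an empty qcCF on the simplex")
    return tuple(c / n for c in counts.counts)


# -- mapping rejected quartets onto the species tree -------------------------------


def _canonical_bipartitions(species: Tree) -> dict[frozenset[str], frozenset[str]]:
    """clade-below-edge -> canonical bipartition side (without min tip)."""
    all_tips = species.tip_labels
    anchor = min(all_tips)
    out = {}
    below: dict[int, frozenset[str]] = {}
    for node in species.root.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        s = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = s
        side = all_tips - s if anchor in s else s
        if 1 < len(side) < len(all_tips) - 1:
            out[s] = side
    return out


def map_rejected_quartets(
    species: Tree, rejected: list[tuple[str, ...]]
) -> dict[frozenset[str], int]:
    """Per-internal-edge counts of rejected quadruples.

    A rejected quadruple increments every internal species-tree edge lying on
    the path that forms the internal edge of its induced quartet (i.e. every
    edge whose bipartition splits the quadruple 2|2).  Edges are keyed by
    their canonical bipartition side.
    """
    tips = species.tip_labels
    edges = _canonical_bipartitions(species)
    counts = {side: 0 for side in set(edges.values())}
    for quad in rejected:
        q = set(quad)
        unknown = q - tips
        if unknown:
            raise KeyError(f"unknown taxa in quadruple: {sorted(unknown)}")
        seen = set()
        for clade, side in edges.items():
            if side in seen:
                continue
            if len(clade & q) == 2 and len(q - clade) == 2:
                counts[side] += 1
                seen.add(side)
    return counts


# -- per-edge quadripartition concordance score ------------------------------------


def eqp_ic(
    species: Tree,
    genes: GeneTreeSet | list[Tree],
    max_exhaustive: int = 2000,
    m_sample: int = 500,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Quadripartition internode-certainty-style score per internal edge.

    Each internal edge defines a quadripartition (A, B, C, D): quartets with
    one taxon per part are aggregated into counts (q1, q2, q3) with q1 the
    resolution joining A with B (the reference).  The score is
    1 + sum_i p_i log3 p_i, negated when the modal resolution is not the
    reference; it is 1 for perfect concordance, 0 at maximum conflict
    (uniform), negative when an alternative dominates.
    """
    trees = list(genes.trees if isinstance(genes, GeneTreeSet) else genes)
    cache = [(t.tip_labels, _tree_clades(t)) for t in trees]
    rng = np.random.default_rng(seed)
    all_tips = species.tip_labels
    below: dict[int, frozenset[str]] = {}
    for node in species.root.postorder():
        below[id(node)] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(below[id(c)] for c in node.children))
        )
    scores: dict[frozenset[str], float] = {}
    anchor = min(all_tips)
    seen_edges: set[frozenset[str]] = set()
    for v in species.internal_nodes(exclude_root=True):
        if len(v.children) != 2:
            continue
        u = v.parent
        A, B = below[id(v.children[0])], below[id(v.children[1])]
        if u is species.root and len(u.children) == 2:
            w = next(c for c in u.children if c is not v)
            if w.is_leaf or len(w.children) != 2:
                continue  # empty fourth part at the unrooted root edge
            C, D = below[id(w.children[0])], below[id(w.children[1])]
        else:
            C = frozenset().union(
                *(below[id(c)] for c in u.children if c is not v)
            )
            D = all_tips - below[id(u)]
            if not C or not D:
                continue
        side = below[id(v)]
        key = all_tips - side if anchor in side else side
        if key in seen_edges:
            continue
        seen_edges.add(key)
        size = len(A) * len(B) * len(C) * len(D)
        if size <= max_exhaustive:
            quads = list(itertools.product(A, B, C, D))
        else:
            quads = [
                (
                    sorted(A)[rng.integers(len(A))],
                    sorted(B)[rng.integers(len(B))],
                    sorted(C)[rng.integers(len(C))],
                    sorted(D)[rng.integers(len(D))],
                )
                for _ in range(m_sample)
            ]
        q = np.zeros(3)
        for a, b, c, d in quads:
            quad = tuple(sorted((a, b, c, d)))
            ref = _resolution_index(quad, frozenset((a, b)))
            alt1 = _resolution_index(quad, frozenset((a, c)))
            alt2 = _resolution_index(quad, frozenset((a, d)))
            for tips, clades in cache:
                if not {a, b, c, d} <= tips:
                    continue
                r = induced_resolution(clades, quad)
                if r == ref:
                    q[0] += 1
                elif r == alt1:
                    q[1] += 1
                elif r == alt2:
                    q[2] += 1
        total = q.sum()
        if total == 0:
            scores[key] = float("nan")
            continue
        p = q / total
        score = 1.0 + sum(pi * math.log(pi, 3) for pi in p if pi > 0)
        if np.argmax(q) != 0:
            score = -score
        scores[key] = float(score)
    return scores
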