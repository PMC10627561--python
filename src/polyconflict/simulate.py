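"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: Yule species trees,
multispecies-coalescent (MSC) gene trees with optional introgression edges,
birth-death duplication/loss homolog trees with optional whole-genome
duplication (WGD), Jukes-Cantor alignments, codon pairs with known synonymous
divergence, and Ks samples from log-normal mixtures.

All generators are bit-reproducible given a seed.  Species-tree branch lengths
are in coalescent units (CU); simulated gene-tree branch lengths are in CU for
the coalescent simulators and follow the species tree for the duplication-loss
simulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trees import GeneTreeSet, Node, TaxonMap, Tree

DEFAULT_TERMINAL_BRANCH_CU = 2.0


@dataclass(frozen=True)
class IntrogressionEdge:
    """A unidirectional gene-flow edge on the species tree.

    ``donor`` and ``recipient`` identify species-tree branches by the tip set
    of the clade the branch subtends (a single tip name is accepted for
    terminal branches).  ``time`` is measured in coalescent units before the
    present; gene lineages sitting in the recipient branch at that time follow
    the donor branch independently with probability ``gamma``.
    """

    donor: frozenset[str] | str
    recipient: frozenset[str] | str
    time: float
    gamma: float

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass(frozen=True)
class DLParams:
    """Duplication-loss simulation parameters (events per CU per lineage)."""

    dup_rate: float = 0.0
    loss_rate: float = 0.0
    wgd_node: frozenset[str] | str | None = None
    retention: float | None = None

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.wgd_node is not None:
            r = self.retention
            if r is None or not 0.0 <= r <= 1.0:
                raise ValueError("WGD retention rate must be in [0,1]")


@dataclass
class SimulatedTruth:
    """Per-gene-tree ground-truth records emitted alongside simulations."""

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


# -- species trees ------------------------------------------------------------


def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Tree:
    """Rooted Yule tree with ``n_taxa`` tips labeled s1..sN (CU branch lengths)."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = Node()
    active: list[tuple[Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node, start = active.pop(int(rng.integers(k)))
        if node is not root:
            node.length = t - start
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for node, start in active:
        node.length = t_end - start
    tree = Tree(root, rooted=True, validate=False)
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"s{i}"
    tree.validate()
    return tree


# -- MSC machinery ------------------------------------------------------------


def _node_by_clade(species: Tree, clade: frozenset[str] | str) -> Node:
    target = frozenset([clade]) if isinstance(clade, str) else frozenset(clade)
    below: dict[int, frozenset[str]] = {}
    for node in species.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if below[id(node)] == target:
            return node
    raise KeyError(f"no species-tree node subtends clade {sorted(target)}")


def _effective_lengths(species: Tree, scale: float, terminal_default: float) -> dict[int, float]:
    """Branch length (x scale) per node id; terminal-branch policy applied."""
    out: dict[int, float] = {}
    for node in species.postorder():
        if node is species.root:
            continue
        if node.length is None:
            if node.is_leaf:
                out[id(node)] = terminal_default * scale
            else:
                raise ValueError(
                    "internal species-tree branch lacks a coalescent-unit length; "
                    "set lengths (or the terminal_branch_length policy only covers tips)"
                )
        else:
            out[id(node)] = node.length * scale
    return out


def _coalesce(
    lineages: list[tuple[Node, float]],
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> list[tuple[Node, float]]:
    """Kingman coalescent among ``lineages`` over [t_start, t_end] (inf allowed).

    Lineages are (gene node, height) pairs; heights grow rootward.
    """
    pool = list(lineages)
    t = t_start
    while len(pool) >= 2:
        k = len(pool)
        t_next = t + rng.exponential(2.0 / (k * (k - 1)))
        if t_next > t_end:
            break
        t = t_next
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(i), int(j)
        (a, ha), (b, hb) = pool[i], pool[j]
        parent = Node()
        a.length = t - ha
        b.length = t - hb
        parent.add_child(a)
        parent.add_child(b)
        pool = [pool[m] for m in range(k) if m not in (i, j)]
        pool.append((parent, t))
    return pool


def simulate_msc_gene_trees(
    species: Tree,
    n_trees: int,
    scale: float = 1.0,
    seed: int = 0,
    terminal_branch_length: float = DEFAULT_TERMINAL_BRANCH_CU,
) -> GeneTreeSet:
    """Single-copy gene trees under the MSC within ``species``.

    One lineage is sampled per species; every species-tree branch length is
    multiplied by ``scale`` before simulation (the plastome test uses 4.0 to
    reflect organellar effective population size).  Terminal branches lacking
    lengths receive ``terminal_branch_length`` CU.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    lengths = _effective_lengths(species, scale, terminal_branch_length)
    post = list(species.postorder())
    trees: list[Tree] = []
    for _ in range(n_trees):
        pools: dict[int, list[tuple[Node, float]]] = {}
        heights: dict[int, float] = {}
        # species node ages (tips contemporaneous at height 0)
        for node in post:
            if node.is_leaf:
                heights[id(node)] = 0.0
        for node in post:
            if not node.is_leaf:
                heights[id(node)] = max(
                    heights[id(c)] + lengths[id(c)] for c in node.children
                )
        for node in post:
            if node.is_leaf:
                entering = [(Node(label=node.label, length=None), 0.0)]
            else:
                entering = []
                for c in node.children:
                    entering.extend(pools[id(c)])
            if node is species.root:
                survivors = _coalesce(entering, heights[id(node)], math.inf, rng)
            else:
                t0 = heights[id(node)]
                survivors = _coalesce(entering, t0, t0 + lengths[id(node)], rng)
                # lineages enter the parent branch at the parent's age
                survivors = [(n, h) for n, h in survivors]
            pools[id(node)] = survivors
        (root_node, _), = pools[id(species.root)]
        root_node.length = None
        trees.append(Tree(root_node, rooted=True, validate=False))
    labels = sorted(species.tip_labels)
    return GeneTreeSet(trees, TaxonMap.identity(labels))


def simulate_network_gene_trees(
    species: Tree,
    edges: list[IntrogressionEdge],
    n_trees: int,
    seed: int = 0,
    scale: float = 1.0,
    terminal_branch_length: float = DEFAULT_TERMINAL_BRANCH_CU,
) -> tuple[GeneTreeSet, SimulatedTruth]:
    """MSC gene trees on a species network (tree + introgression edges).

    The simulation runs in continuous absolute time (tipward heights).  At each
    introgression event, every gene lineage currently in the recipient branch
    independently jumps to the donor branch with probability gamma.
    """
    rng = np.random.default_rng(seed)
    lengths = _effective_lengths(species, scale, terminal_branch_length)
    post = list(species.postorder())
    heights: dict[int, float] = {}
    for node in post:
        heights[id(node)] = (
            0.0
            if node.is_leaf
            else max(heights[id(c)] + lengths[id(c)] for c in node.children)
        )

    def interval(node: Node) -> tuple[float, float]:
        lo = heights[id(node)]
        hi = math.inf if node is species.root else lo + lengths[id(node)]
        return lo, hi

    resolved = []
    for e in edges:
        donor = _node_by_clade(species, e.donor)
        recip = _node_by_clade(species, e.recipient)
        t = e.time * scale
        for nd, name in ((donor, "donor"), (recip, "recipient")):
            lo, hi = interval(nd)
            if not lo <= t <= hi:
                raise ValueError(
                    f"introgression time {e.time} outside the {name} branch "
                    f"interval [{lo / scale:.4g}, {hi / scale:.4g}] CU"
                )
        resolved.append((t, donor, recip, e.gamma))

    # event timeline: species nodes (merges) then introgression jumps
    merge_events = [(heights[id(n)], 0, n) for n in post if not n.is_leaf]
    flow_events = [(t, 1, idx) for idx, (t, *_rest) in enumerate(resolved)]
    timeline = sorted(merge_events + flow_events, key=lambda ev: (ev[0], ev[1]))

    trees: list[Tree] = []
    truth = SimulatedTruth()
    for tree_idx in range(n_trees):
        pools: dict[int, list[tuple[Node, float]]] = {
            id(n): [] for n in post if not n.is_leaf
        }
        clocks: dict[int, float] = {}
        for node in post:
            if node.is_leaf:
                pools[id(node)] = [(Node(label=node.label), 0.0)]
                clocks[id(node)] = 0.0
            else:
                clocks[id(node)] = heights[id(node)]
        moved: dict[int, list[list[str]]] = {}

        def advance(branch: Node, t_to: float) -> None:
            pools[id(branch)] = _coalesce(
                pools[id(branch)], clocks[id(branch)], min(t_to, interval(branch)[1]), rng
            )
            clocks[id(branch)] = t_to

        for t_ev, kind, payload in timeline:
            for node in post:  # bring every active branch up to t_ev
                if interval(node)[0] <= t_ev and clocks[id(node)] < t_ev:
                    advance(node, t_ev)
            if kind == 0:
                node = payload
                entering = []
                for c in node.children:
                    entering.extend(pools[id(c)])
                    pools[id(c)] = []
                pools[id(node)].extend(entering)
            else:
                _t, donor, recip, gamma = resolved[payload]
                staying, jumping = [], []
                for lin in pools[id(recip)]:
                    (jumping if rng.random() < gamma else staying).append(lin)
                pools[id(recip)] = staying
                pools[id(donor)].extend(jumping)
                if jumping:
                    moved.setdefault(payload, []).extend(
                        sorted(tip.label for tip in lin[0].leaves()) for lin in jumping
                    )
        # final coalescent in the root branch
        root = species.root
        pools[id(root)] = _coalesce(pools[id(root)], clocks[id(root)], math.inf, rng)
        (root_node, _), = pools[id(root)]
        root_node.length = None
        trees.append(Tree(root_node, rooted=True, validate=False))
        truth.records.append(
            {"tree": tree_idx, "introgressed": {k: v for k, v in moved.items()}}
        )
    labels = sorted(species.tip_labels)
    return GeneTreeSet(trees, TaxonMap.identity(labels)), truth


# -- duplication-loss gene trees ----------------------------------------------


def simulate_dl_gene_trees(
    species: Tree,
    params: DLParams,
    n_trees: int,
    seed: int = 0,
) -> tuple[GeneTreeSet, SimulatedTruth]:
    """Multi-copy homolog trees under top-down birth-death duplication/loss.

    A single ancestral gene enters at the species-tree root.  Along each
    species branch, every gene lineage duplicates at ``dup_rate`` and is lost
    at ``loss_rate``.  At the WGD node (if any) every lineage duplicates and
    the extra copy is retained with probability ``retention``.  Gene copies
    are named ``species@k``; trees losing every copy are redrawn (and counted).
    """
    rng = np.random.default_rng(seed)
    wgd = _node_by_clade(species, params.wgd_node) if params.wgd_node is not None else None
    if wgd is not None and wgd.is_leaf:
        raise ValueError("WGD node must be an internal species-tree node")
    total = params.dup_rate + params.loss_rate
    clade_of: dict[int, frozenset[str]] = {}
    for node in species.postorder():
        clade_of[id(node)] = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(clade_of[id(c)] for c in node.children))
        )

    def through_node(sp: Node, events: list) -> Node | None:
        """Pass one gene lineage through species node ``sp`` (tipward)."""
        if sp.is_leaf:
            return Node(label=sp.label, length=0.0)
        copies = 1
        if sp is wgd:
            copies = 2 if rng.random() < params.retention else 1
            events.append(("wgd", clade_of[id(sp)], copies == 2))
        subtrees = []
        for _ in range(copies):
            kids = []
            for child in sp.children:
                sub = down_branch(child, child.length if child.length is not None else 0.0, events)
                if sub is not None:
                    kids.append(sub)
            if not kids:
                continue
            if len(kids) == 1:
                subtrees.append(kids[0])
            else:
                spec = Node(length=0.0)
                for k in kids:
                    spec.add_child(k)
                subtrees.append(spec)
        if not subtrees:
            return None
        if len(subtrees) == 1:
            return subtrees[0]
        dup = Node(length=0.0)
        for s in subtrees:
            dup.add_child(s)
        return dup

    def down_branch(sp: Node, remaining: float, events: list) -> Node | None:
        """Evolve one gene lineage down ``sp``'s subtending branch."""
        consumed = 0.0
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            if wait >= remaining:
                sub = through_node(sp, events)
                if sub is not None:
                    sub.length = (sub.length or 0.0) + remaining + consumed
                return sub
            remaining -= wait
            consumed += wait
            if rng.random() < params.loss_rate / total:
                events.append(("loss", clade_of[id(sp)]))
                return None
            events.append(("dup", clade_of[id(sp)]))
            left = down_branch(sp, remaining, events)
            right = down_branch(sp, remaining, events)
            if left is None and right is None:
                return None
            if left is None or right is None:
                sub = left if right is None else right
                sub.length = (sub.length or 0.0) + consumed
                return sub
            dup = Node(length=consumed)
            dup.add_child(left)
            dup.add_child(right)
            return dup

    trees: list[Tree] = []
    truth = SimulatedTruth()
    mapping: dict[str, str] = {}
    n_extinct = 0
    while len(trees) < n_trees:
        events: list = []
        root_sub = through_node(species.root, events)
        if root_sub is None:
            n_extinct += 1
            continue
        root_sub.length = None
        counters: dict[str, int] = {}
        for tip in root_sub.leaves():
            sp = tip.label
            counters[sp] = counters.get(sp, 0) + 1
            tip.label = f"{sp}@{counters[sp]}"
            mapping[tip.label] = sp
        tree = Tree(root_sub, rooted=True, validate=False)
        tree.suppress_unifurcations()
        trees.append(tree)
        truth.records.append(
            {
                "tree": len(trees) - 1,
                "duplications": [sorted(c) for ev, c, *_ in events if ev == "dup"],
                "losses": sum(1 for ev, *_ in events if ev == "loss"),
                "wgd_retained": next(
                    (e[2] for e in events if e[0] == "wgd"), None
                ),
            }
        )
    truth.records.append({"n_extinct_redrawn": n_extinct})
    return GeneTreeSet(trees, TaxonMap(mapping)), truth


# -- alignments ----------------------------------------------------------------

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Alignment:
    """A simple in-memory nucleotide alignment (rows x sites, uint8 0..3)."""

    names: list[str]
    data: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 2 or len(self.names) != self.data.shape[0]:
            raise ValueError("data must be (n_seqs, length) with one row per name")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def row(self, name: str) -> np.ndarray:
        try:
            return self.data[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no alignment row for taxon {name!r}")

    def sequence(self, name: str) -> str:
        return _NUC[self.row(name)].tobytes().decode()

    def to_fasta(self, path: str) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequence(n)), id=n, description="") for n in self.names
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        from Bio import SeqIO

        names, rows = [], []
        code = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            code[b] = i
            code[b + 32] = i
        for rec in SeqIO.parse(path, "fasta"):
            names.append(rec.id)
            raw = np.frombuffer(str(rec.seq).encode(), dtype=np.uint8)
            rows.append(code[raw])
        if not names:
            raise ValueError(f"no sequences in {path}")
        return cls(names, np.vstack(rows))


def simulate_alignment(
    gene_tree: Tree, length: int, model: str = "JC69", seed: int = 0
) -> Alignment:
    """Evolve an alignment along ``gene_tree`` under Jukes-Cantor.

    Branch lengths are in substitutions/site.  Sites marked 255 never occur;
    all characters are A/C/G/T.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    if model != "JC69":
        raise ValueError(f"unsupported model {model!r} (only JC69)")
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.integers(0, 4, size=length, dtype=np.uint8)
    }
    names, rows = [], []
    for node in gene_tree.preorder():
        if node is gene_tree.root:
            parent_seq = seqs[id(node)]
        else:
            d = node.length or 0.0
            p_same = 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
            parent_seq = seqs[id(node.parent)]
            child = parent_seq.copy()
            hit = rng.random(length) >= p_same
            n_hit = int(hit.sum())
            if n_hit:
                child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit, dtype=np.uint8)) % 4
            seqs[id(node)] = child
        if node.is_leaf:
            names.append(node.label)
            rows.append(seqs[id(node)])
    return Alignment(names, np.vstack(rows) if rows else np.zeros((0, length), np.uint8))


# -- codon pairs ---------------------------------------------------------------


def simulate_codon_pairs(
    ks_true: float,
    ka_true: float,
    n_codons: int,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """A codon-sequence pair with known synonymous/nonsynonymous divergence.

    Substitution events are placed on NG86-defined synonymous/nonsynonymous
    sites at Poisson rates giving expected per-site divergences ``ks_true``
    and ``ka_true`` (multiple hits allowed, so the Jukes-Cantor correction in
    the estimator is exercised).  No stop codons are ever emitted.  Returns
    (seq1, seq2, truth) where truth records the realized event counts.
    """
    from .ks import SENSE_CODONS, codon_site_counts, one_step_changes

    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if ks_true < 0 or ka_true < 0:
        raise ValueError("divergences must be >= 0")
    expected_ps = 0.75 * (1.0 - math.exp(-4.0 * ks_true / 3.0))
    if expected_ps >= 0.70:
        warnings.warn(
            "expected synonymous divergence is near saturation; the NG86 "
            "estimator will be undefined for some replicates",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    anc = list(codons)

    syn_sites = np.array([codon_site_counts(c)[0] for c in codons])
    non_sites = np.array([codon_site_counts(c)[1] for c in codons])
    n_syn_events = int(rng.poisson(ks_true * syn_sites.sum()))
    n_non_events = int(rng.poisson(ka_true * non_sites.sum()))

    def apply_events(n_events: int, synonymous: bool, weights: np.ndarray) -> int:
        # rejection sampling: per-codon site weights are bounded by 3
        applied = 0
        for _ in range(n_events):
            if weights.sum() <= 0:
                break
            while True:
                pos = int(rng.integers(n_codons))
                if rng.random() * 3.0 < weights[pos]:
                    break
            options = [
                alt
                for alt, is_syn in one_step_changes(codons[pos])
                if is_syn == synonymous
            ]
            if not options:
                continue
            codons[pos] = options[int(rng.integers(len(options)))]
            s, n = codon_site_counts(codons[pos])
            syn_sites[pos], non_sites[pos] = s, n
            applied += 1
        return applied

    applied_syn = apply_events(n_syn_events, True, syn_sites)
    applied_non = apply_events(n_non_events, False, non_sites)
    truth = {
        "syn_events": applied_syn,
        "nonsyn_events": applied_non,
        "syn_sites_ancestral": float(
            sum(codon_site_counts(c)[0] for c in anc)
        ),
    }
    return "".join(anc), "".join(codons), truth


# -- Ks mixtures ---------------------------------------------------------------


def simulate_ks_mixture(
    means: list[float],
    sds: list[float],
    weights: list[float],
    n: int,
    seed: int = 0,
    window: tuple[float, float] = (0.05, 3.0),
) -> np.ndarray:
    """Draws from a log-normal mixture, truncated to ``window`` with resampling.

    ``means`` are component medians on the natural Ks scale; ``sds`` are
    standard deviations on the log scale.
    """
    if not (len(means) == len(sds) == len(weights)):
        raise ValueError("means, sds and weights must have the same length")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    lo, hi = window
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(means), size=m, p=w)
        draws = np.exp(
            np.log(np.asarray(means))[comp] + np.asarray(sds)[comp] * rng.standard_normal(m)
        )
        ok = draws[(draws >= lo) & (draws <= hi)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out
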