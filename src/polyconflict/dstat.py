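"""ABBA-BABA D-statistic tests for ancient introgression.

For a four-taxon design (((P1, P2), P3), O), biallelic site patterns where
P2 shares the derived allele with P3 (ABBA) should be as frequent as patterns
where P1 shares it (BABA) under ILS alone; an excess of one class, measured by
D = (nABBA - nBABA)/(nABBA + nBABA), indicates introgression.  Significance
uses a site-resampling bootstrap Z score, with Holm-Bonferroni correction
across all taxon combinations of a design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import Alignment


@dataclass(frozen=True)
class FourTaxonDesign:
    """Named groups of taxa for a (((P1, P2), P3), O) test design."""

    p1: frozenset[str]
    p2: frozenset[str]
    p3: frozenset[str]
    outgroup: frozenset[str]
    design_id: str = "design"

    def __post_init__(self):
        groups = [self.p1, self.p2, self.p3, self.outgroup]
        if any(not g for g in groups):
            raise ValueError("all four groups must be non-empty")
        for a, b in itertools.combinations(groups, 2):
            if a & b:
                raise ValueError(f"groups overlap: {sorted(a & b)}")

    def combinations(self) -> list[tuple[str, str, str, str]]:
        return [
            (a, b, c, d)
            for a in sorted(self.p1)
            for b in sorted(self.p2)
            for c in sorted(self.p3)
            for d in sorted(self.outgroup)
        ]


@dataclass
class DStatResult:
    combination: tuple[str, str, str, str]
    n_abba: int
    n_baba: int
    d: float
    sd: float
    z: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
    defined: bool = True


def _site_categories(
    alignment: Alignment, p1: str, p2: str, p3: str, o: str
) -> np.ndarray:
    """Per-site category: 1=ABBA, 2=BABA, 0=other/skipped.

    Only gap-free, strictly biallelic four-row configurations count; the
    outgroup state is ancestral (A), the single alternative state derived (B).
    """
    rows = np.stack([alignment.row(t) for t in (p1, p2, p3, o)])
    valid = (rows < 4).all(axis=0)
    r1, r2, r3, ro = rows
    eq13, eq23 = r1 == r3, r2 == r3
    eq1o, eq2o = r1 == ro, r2 == ro
    # biallelic among the four rows: exactly two distinct states
    sorted_rows = np.sort(rows, axis=0)
    distinct = 1 + (np.diff(sorted_rows, axis=0) != 0).sum(axis=0)
    biallelic = valid & (distinct == 2)
    abba = biallelic & eq1o & ~eq2o & eq23
    baba = biallelic & eq2o & ~eq1o & eq13
    out = np.zeros(alignment.length, dtype=np.int8)
    out[abba] = 1
    out[baba] = 2
    return out


def count_site_patterns(
    alignment: Alignment, p1: str, p2: str, p3: str, o: str
) -> tuple[int, int]:
    """ABBA and BABA counts for one taxon combination."""
    cats = _site_categories(alignment, p1, p2, p3, o)
    return int((cats == 1).sum()), int((cats == 2).sum())


def d_statistic(n_abba: int, n_baba: int) -> float:
    """(nABBA - nBABA)/(nABBA + nBABA); NaN when undefined."""
    total = n_abba + n_baba
    if total == 0:
        return float("nan")
    return (n_abba - n_baba) / total


def bootstrap_z(
    alignment: Alignment,
    combination: tuple[str, str, str, str],
    n_boot: int = 200,
    block: int = 1,
    seed: int = 0,
) -> DStatResult:
    """D with a site-resampling bootstrap SD, Z score and two-tailed p.

    Alignment columns are resampled with replacement in blocks of ``block``
    sites.  A degenerate bootstrap (SD = 0) with nonzero D yields Z = +/-inf
    and p = 0.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    cats = _site_categories(alignment, *combination)
    n_abba, n_baba = int((cats == 1).sum()), int((cats == 2).sum())
    d_obs = d_statistic(n_abba, n_baba)
    if math.isnan(d_obs):
        return DStatResult(combination, n_abba, n_baba, float("nan"), float("nan"),
                           float("nan"), float("nan"), defined=False)
    rng = np.random.default_rng(seed)
    L = len(cats)
    n_blocks = math.ceil(L / block)
    if block == 1:
        # resampling sites == multinomial resampling of category totals
        p = np.array([(cats == 1).sum(), (cats == 2).sum(), (cats == 0).sum()]) / L
        draws = rng.multinomial(L, p, size=n_boot).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_boot = (draws[:, 0] - draws[:, 1]) / (draws[:, 0] + draws[:, 1])
    else:
        block_abba = np.add.reduceat(cats == 1, np.arange(0, L, block))
        block_baba = np.add.reduceat(cats == 2, np.arange(0, L, block))
        idx = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
        tot_abba = block_abba[idx].sum(axis=1).astype(float)
        tot_baba = block_baba[idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_boot = (tot_abba - tot_baba) / (tot_abba + tot_baba)
    d_boot = d_boot[np.isfinite(d_boot)]
    sd = float(np.std(d_boot, ddof=1)) if len(d_boot) > 1 else 0.0
    if sd == 0.0:
        z = math.inf * np.sign(d_obs) if d_obs != 0 else 0.0
        p = 0.0 if d_obs != 0 else 1.0
    else:
        z = d_obs / sd
        p = 2.0 * stats.norm.sf(abs(z))
    return DStatResult(combination, n_abba, n_baba, float(d_obs), sd, float(z), float(p))


def holm_bonferroni(pvalues: list[float]) -> list[float]:
    """Step-down Holm-Bonferroni adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


@dataclass
class DesignSummary:
    design_id: str
    n_combinations: int
    n_significant: int
    fraction_significant: float
    category: str  # "significant gene flow" | "insignificant" | "ambiguous"
    results: list[DStatResult] = field(default_factory=list)


def run_design(
    alignment: Alignment,
    design: FourTaxonDesign,
    z_thresh: float = 3.0,
    alpha: float = 0.05,
    n_boot: int = 200,
    block: int = 1,
    seed: int = 0,
) -> DesignSummary:
    """D-statistic battery over every taxon combination of a design.

    All member combinations (Cartesian product of the four groups) are tested;
    Holm-Bonferroni is applied across the design.  A combination is counted as
    significant when Z > ``z_thresh`` AND adjusted p < ``alpha``; the design is
    summarized as "significant gene flow" when more than half of combinations
    are significant, "insignificant" when fewer than 10% are, and "ambiguous"
    in between.
    """
    combos = design.combinations()
    if not combos:
        raise ValueError("design yields no combinations")
    rng = np.random.default_rng(seed)
    results = [
        bootstrap_z(alignment, combo, n_boot=n_boot, block=block,
                    seed=int(rng.integers(2**31)))
        for combo in combos
    ]
    defined = [r for r in results if r.defined]
    adjusted = holm_bonferroni([r.p_value for r in defined])
    n_sig = 0
    for r, padj in zip(defined, adjusted):
        r.p_adjusted = padj
        r.significant = (r.z > z_thresh) and (padj < alpha)
        n_sig += r.significant
    frac = n_sig / len(combos)
    if frac > 0.5:
        category = "significant gene flow"
    elif frac < 0.1:
        category = "insignificant"
    else:
        category = "ambiguous"
    return DesignSummary(design.design_id, len(combos), n_sig, frac, category, results)


def read_design_tsv(path: str, design_id: str = "design") -> FourTaxonDesign:
    """Read a two-column TSV (group, taxon); groups P1, P2, P3, O."""
    groups: dict[str, set[str]] = {"P1": set(), "P2": set(), "P3": set(), "O": set()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            group, taxon = line.split("\t")[:2]
            if group not in groups:
                raise ValueError(f"unknown group {group!r} (expected P1/P2/P3/O)")
            groups[group].add(taxon)
    return FourTaxonDesign(
        frozenset(groups["P1"]), frozenset(groups["P2"]),
        frozenset(groups["P3"]), frozenset(groups["O"]), design_id,
    )
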