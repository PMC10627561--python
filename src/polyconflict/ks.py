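"""Synonymous-substitution (Ks) estimation and mixture-model peak detection.

Ks/Ka are estimated with the Nei-Gojobori (NG86) counting method with
Jukes-Cantor correction.  Paleopolyploidy peaks are detected by fitting
Gaussian mixtures to log-Ks with EM and selecting the number of components by
BIC; within-orthogroup paralog/ortholog divergence is compared with a Welch
unpaired t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .trees import TaxonMap

# standard genetic code via biopython
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: list[str] = sorted(CODON_TO_AA)
_BASES = "ACGT"


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    Each position contributes (number of synonymous one-step changes)/3
    synonymous sites; changes to stop codons count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def one_step_changes(codon: str) -> tuple[tuple[str, bool], ...]:
    """All single-nucleotide neighbors of a sense codon that are themselves
    sense codons, tagged synonymous/nonsynonymous."""
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            out.append((alt, CODON_TO_AA[alt] == aa))
    return tuple(out)


@lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two sense
    codons over all minimal substitution pathways.

    Pathways passing through a stop codon get weight zero; if every pathway
    hits a stop, all pathways are used with stop-creating steps counted as
    nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1.0
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_pos))
    results = [r for r in (walk(o, False) for o in orders) if r is not None]
    if not results:
        results = [walk(o, True) for o in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


@dataclass
class KsEstimate:
    """NG86 site and difference counts with Jukes-Cantor-corrected Ks/Ka."""

    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float
    ka: float
    defined: bool
    n_codons: int = 0


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), False
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), True


def ng86_ks(seq1: str, seq2: str, pair_id: str = "") -> KsEstimate:
    """Pairwise NG86 Ks/Ka for two equal-length, codon-aligned sequences.

    Codons containing characters outside ACGT, gaps, or stop codons (in
    either sequence) are skipped.  Ks is undefined (``defined=False``) when
    the synonymous divergence saturates (pS >= 3/4).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    seq1, seq2 = seq1.upper(), seq2.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in CODON_TO_AA or c2 not in CODON_TO_AA:
            continue
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
        n_codons += 1
    if S <= 0 or N <= 0:
        return KsEstimate(pair_id, S, N, Sd, Nd, float("nan"), float("nan"),
                          float("nan"), float("nan"), False, n_codons)
    pS, pN = Sd / S, Nd / N
    ks, ks_ok = _jc_correct(pS)
    ka, ka_ok = _jc_correct(pN)
    return KsEstimate(pair_id, S, N, Sd, Nd, pS, pN, ks, ka, ks_ok and ka_ok, n_codons)


# -- pair tables ----------------------------------------------------------------


def build_ks_table(
    orthogroups: Mapping[str, Mapping[str, str]],
    taxon_map: TaxonMap,
    pair_type: str = "paralog",
    species_pair: tuple[str, str] | None = None,
    window: tuple[float, float] = (0.05, 3.0),
) -> pd.DataFrame:
    """One NG86 Ks estimate per eligible pair, filtered to ``window``.

    ``orthogroups`` maps orthogroup id -> {gene copy label -> codon-aligned
    sequence}.  ``pair_type='paralog'`` pairs copies within one species;
    ``pair_type='ortholog'`` pairs copies between the two species named in
    ``species_pair``.  Undefined or out-of-window estimates are excluded (the
    count is recorded in ``df.attrs['n_excluded']``).
    """
    if pair_type not in ("paralog", "ortholog"):
        raise ValueError("pair_type must be 'paralog' or 'ortholog'")
    if pair_type == "ortholog" and species_pair is None:
        raise ValueError("ortholog tables need a species_pair")
    lo, hi = window
    rows = []
    n_excluded = 0
    for og_id, seqs in orthogroups.items():
        labels = sorted(seqs)
        for a, b in itertools.combinations(labels, 2):
            sp_a, sp_b = taxon_map.species_of(a), taxon_map.species_of(b)
            if pair_type == "paralog":
                if sp_a != sp_b:
                    continue
            else:
                if {sp_a, sp_b} != set(species_pair):
                    continue
            est = ng86_ks(seqs[a], seqs[b], pair_id=f"{a}|{b}")
            if not est.defined or not (lo <= est.ks <= hi):
                n_excluded += 1
                continue
            rows.append(
                {
                    "orthogroup": og_id,
                    "copy1": a,
                    "copy2": b,
                    "species1": sp_a,
                    "species2": sp_b,
                    "pair_type": pair_type,
                    "ks": est.ks,
                    "ka": est.ka,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["orthogroup", "copy1", "copy2", "species1", "species2",
                 "pair_type", "ks", "ka"],
    )
    df.attrs["n_excluded"] = n_excluded
    return df


# -- mixture modeling ------------------------------------------------------------


@dataclass
class MixtureFit:
    """A BIC-selected Gaussian mixture on log-Ks.

    ``means``/``sds``/``weights`` are on the log scale, sorted by mean;
    ``modes`` are the back-transformed component medians (exp of the means).
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    modes: np.ndarray
    bic: dict[int, float]
    log_likelihood: float
    _model: object = field(default=None, repr=False)

    def posteriors(self, ks: np.ndarray) -> np.ndarray:
        """Component membership posteriors (columns ordered as ``means``)."""
        x = np.log(np.asarray(ks, dtype=float)).reshape(-1, 1)
        resp = self._model.predict_proba(x)
        return resp[:, self._order]


def fit_gmm(
    ks: Iterable[float],
    k_range: Iterable[int] = range(1, 6),
    seed: int = 0,
    n_restarts: int = 10,
) -> MixtureFit:
    """Fit Gaussian mixtures to log-Ks and select k by BIC.

    EM with k-means initialization (``n_restarts`` starts per k);
    BIC = -2 LL + (3k - 1) ln n.
    """
    from sklearn.mixture import GaussianMixture

    ks = np.asarray(list(ks), dtype=float)
    k_range = list(k_range)
    if len(ks) < 10 * max(k_range):
        raise ValueError(
            f"need >= {10 * max(k_range)} values to test up to k={max(k_range)}"
        )
    x = np.log(ks).reshape(-1, 1)
    best = None
    bics: dict[int, float] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            init_params="kmeans",
            random_state=seed,
        ).fit(x)
        bics[k] = float(gm.bic(x))
        if best is None or bics[k] < bics[best[0]]:
            best = (k, gm)
    k, gm = best
    means = gm.means_.ravel()
    order = np.argsort(means)
    fit = MixtureFit(
        k=k,
        means=means[order],
        sds=np.sqrt(gm.covariances_.reshape(k)[order]),
        weights=gm.weights_[order],
        modes=np.exp(means[order]),
        bic=bics,
        log_likelihood=float(gm.score(x) * len(x)),
        _model=gm,
    )
    fit._order = order
    return fit


@dataclass
class KsComparison:
    """Welch t-test comparison of paralog vs ortholog Ks distributions."""

    mean_paralog: float
    var_paralog: float
    n_paralog: int
    mean_ortholog: float
    var_ortholog: float
    n_ortholog: int
    t_statistic: float
    p_value: float
    direction: str
    defined: bool


def within_orthogroup_compare(
    paralog_table: pd.DataFrame,
    ortholog_table: pd.DataFrame,
    posterior_min: float = 0.95,
    seed: int = 0,
) -> KsComparison:
    """Compare paralog vs ortholog Ks restricted to shared orthogroups.

    To avoid rate variation among genes, only orthogroups present in both
    tables contribute.  Each table is isolated to its dominant (highest
    weight) mixture component: pairs are kept only when their posterior
    membership in that component is >= ``posterior_min``.  A single-component
    fit keeps everything.  Means are compared with a Welch unpaired t-test.
    """

    shared = set(paralog_table["orthogroup"]) & set(ortholog_table["orthogroup"])
    par = paralog_table[paralog_table["orthogroup"].isin(shared)]
    ort = ortholog_table[ortholog_table["orthogroup"].isin(shared)]

    def isolate(df: pd.DataFrame) -> np.ndarray:
        vals = df["ks"].to_numpy()
        if len(vals) >= 20:
            try:
                fit = fit_gmm(vals, k_range=range(1, min(4, len(vals) // 10) + 1), seed=seed)
            except ValueError:
                return vals
            if fit.k > 1:
                comp = int(np.argmax(fit.weights))
                post = fit.posteriors(vals)[:, comp]
                return vals[post >= posterior_min]
        return vals

    par_ks, ort_ks = isolate(par), isolate(ort)
    if len(par_ks) < 2 or len(ort_ks) < 2:
        return KsComparison(
            float("nan"), float("nan"), len(par_ks),
            float("nan"), float("nan"), len(ort_ks),
            float("nan"), float("nan"), "undefined", False,
        )
    t, p = stats.ttest_ind(par_ks, ort_ks, equal_var=False)
    direction = "paralogs_older" if par_ks.mean() > ort_ks.mean() else "paralogs_younger"
    return KsComparison(
        float(par_ks.mean()), float(par_ks.var(ddof=1)), len(par_ks),
        float(ort_ks.mean()), float(ort_ks.var(ddof=1)), len(ort_ks),
        float(t), float(p), direction, True,
    )
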