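"""Coalescent plastome-simulation test for cytonuclear discordance.

If incomplete lineage sorting (ILS) alone explains a conflict between the
nuclear species tree and the plastid tree, the plastid tree's clades should
appear at appreciable frequency among gene trees simulated under the MSC on
the nuclear tree (with branch lengths scaled up because the uniparentally
inherited plastome has a smaller effective population size).  Unique plastid
clades found at very low simulated frequency cannot be explained by ILS and
point to hybridization.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import DEFAULT_TERMINAL_BRANCH_CU, simulate_msc_gene_trees
from .trees import TipSetMismatchError, Tree, clade_frequencies


@dataclass
class CladeRecord:
    clade: frozenset[str]
    shared_with_nuclear: bool
    frequency: float
    classification: str  # "shared", "ILS-plausible", or "ILS-implausible"


@dataclass
class IlsTestReport:
    records: list[CladeRecord]
    n_sim: int
    scale: float
    threshold: float

    def unique_clades(self) -> list[CladeRecord]:
        return [r for r in self.records if not r.shared_with_nuclear]

    def implausible(self) -> list[CladeRecord]:
        return [r for r in self.records if r.classification == "ILS-implausible"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clade": [",".join(sorted(r.clade)) for r in self.records],
                "n_tips": [len(r.clade) for r in self.records],
                "shared_with_nuclear": [r.shared_with_nuclear for r in self.records],
                "frequency": [r.frequency for r in self.records],
                "classification": [r.classification for r in self.records],
            }
        )


def plastome_ils_test(
    nuclear: Tree,
    plastid: Tree,
    n_sim: int = 10000,
    scale: float = 4.0,
    threshold: float = 0.15,
    seed: int = 0,
    terminal_branch_length: float = DEFAULT_TERMINAL_BRANCH_CU,
) -> IlsTestReport:
    """Simulate ``n_sim`` plastome trees under the MSC on the nuclear tree and
    summarize each plastid clade's frequency among them.

    The nuclear tree needs coalescent-unit branch lengths (terminal branches
    lacking one receive ``terminal_branch_length`` CU).  A plastid clade absent
    from the nuclear topology ("unique") whose simulated frequency is at or
    below ``threshold`` is classified ILS-implausible.
    """
    if nuclear.tip_labels != plastid.tip_labels:
        raise TipSetMismatchError(
            f"nuclear/plastid tip sets differ: {sorted(nuclear.tip_labels ^ plastid.tip_labels)}"
        )
    sims = simulate_msc_gene_trees(
        nuclear, n_sim, scale=scale, seed=seed,
        terminal_branch_length=terminal_branch_length,
    )
    freqs = clade_frequencies(plastid, sims.trees, rooted=True)
    nuclear_clades = nuclear.clade_sets()
    records = []
    for clade in sorted(freqs, key=lambda c: (len(c), sorted(c))):
        shared = clade in nuclear_clades
        freq = freqs[clade]
        if shared:
            cls = "shared"
        elif freq <= threshold:
            cls = "ILS-implausible"
        else:
            cls = "ILS-plausible"
        records.append(CladeRecord(clade, shared, freq, cls))
    return IlsTestReport(records, n_sim, scale, threshold)
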