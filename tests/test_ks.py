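import math

import numpy as np
import pytest

from polyconflict.ks import (
    build_ks_table,
    fit_gmm,
    ng86_ks,
    within_orthogroup_compare,
)
from polyconflict.simulate import simulate_codon_pairs, simulate_ks_mixture
from polyconflict.trees import TaxonMap


class TestNg86:
    def test_identical_sequences(self):
        est = ng86_ks("ATGGCT" * 20, "ATGGCT" * 20)
        assert est.ks == 0.0 and est.ka == 0.0 and est.defined

    def test_hand_enumerated_lysine_toy(self):
        """AAA x10 vs AAG+AAA x9: S=10/3, Sd=1, pS=0.3, Ks=-0.75 ln 0.6."""
        est = ng86_ks("AAA" * 10, "AAG" + "AAA" * 9)
        assert est.S == pytest.approx(10 / 3)
        assert est.Sd == pytest.approx(1.0)
        assert est.pS == pytest.approx(0.3)
        assert est.ks == pytest.approx(-0.75 * math.log(0.6), rel=1e-12)
        assert est.ka == 0.0

    def test_symmetry(self):
        s1, s2, _ = simulate_codon_pairs(0.4, 0.2, 150, seed=1)
        a, b = ng86_ks(s1, s2), ng86_ks(s2, s1)
        assert a.ks == pytest.approx(b.ks) and a.ka == pytest.approx(b.ka)
        assert a.S == pytest.approx(b.S)

    def test_length_errors(self):
        with pytest.raises(ValueError):
            ng86_ks("ATGG", "ATGG")
        with pytest.raises(ValueError):
            ng86_ks("ATG", "ATGATG")

    def test_ambiguous_codons_skipped(self):
        est_clean = ng86_ks("AAAGGG", "AAGGGG")
        est_with_n = ng86_ks("AAAGGGANA", "AAGGGGAAA")
        assert est_with_n.n_codons == est_clean.n_codons == 2

    def test_saturation_undefined(self):
        # wildly divergent synonymous third positions cannot stay below 3/4
        est = ng86_ks("TTA" * 30, "CTG" * 30)
        assert not est.defined or est.ks > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_biopython_ng86(self, seed):
        """Independent oracle: Bio.codonalign's NG86 implementation."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        s1, s2, _ = simulate_codon_pairs(0.3, 0.15, 120, seed=seed)
        dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
        est = ng86_ks(s1, s2)
        assert est.ks == pytest.approx(ds, abs=1e-9)
        assert est.ka == pytest.approx(dn, abs=1e-9)

    def test_estimator_recovers_truth(self):
        vals = []
        for seed in range(15):
            s1, s2, _ = simulate_codon_pairs(0.2, 0.05, 3000, seed=seed)
            vals.append(ng86_ks(s1, s2).ks)
        assert abs(np.mean(vals) - 0.2) < 0.02


class TestBuildKsTable:
    def _orthogroups(self):
        pairs = {}
        seqs = {}
        for i, sp in enumerate(["spA", "spA", "spA", "spB"]):
            s1, _, _ = simulate_codon_pairs(0.0, 0.0, 60, seed=i)
            seqs[f"{sp}@{i}"] = s1
        # make divergent copies within one orthogroup
        base, div, _ = simulate_codon_pairs(0.3, 0.05, 60, seed=99)
        og = {"spA@1": base, "spA@2": div, "spA@3": base, "spB@1": base}
        return {"og1": og}

    def test_paralog_pair_combinatorics(self):
        ogs = self._orthogroups()
        tmap = TaxonMap.from_copy_labels(ogs["og1"])
        table = build_ks_table(ogs, tmap, "paralog", window=(0.0, 3.0))
        # 3 spA copies -> 3 paralog pairs (identical pairs give ks=0, kept by window)
        assert len(table) == 3

    def test_single_copy_species_no_paralogs(self):
        base, _, _ = simulate_codon_pairs(0.0, 0.0, 60, seed=0)
        ogs = {"og1": {"spA@1": base, "spB@1": base}}
        tmap = TaxonMap.from_copy_labels(ogs["og1"])
        assert len(build_ks_table(ogs, tmap, "paralog")) == 0

    def test_window_filter(self):
        ogs = self._orthogroups()
        tmap = TaxonMap.from_copy_labels(ogs["og1"])
        table = build_ks_table(ogs, tmap, "paralog", window=(0.05, 3.0))
        assert (table["ks"] >= 0.05).all()
        assert table.attrs["n_excluded"] == 1  # the identical spA@1-spA@3 pair

    def test_ortholog_pairs_need_species_pair(self):
        ogs = self._orthogroups()
        tmap = TaxonMap.from_copy_labels(ogs["og1"])
        with pytest.raises(ValueError):
            build_ks_table(ogs, tmap, "ortholog")
        table = build_ks_table(ogs, tmap, "ortholog", ("spA", "spB"), window=(0.0, 3.0))
        assert len(table) == 3  # 3 spA copies x 1 spB copy


class TestFitGmm:
    def test_single_component_selected(self):
        vals = simulate_ks_mixture([0.3], [0.15], [1.0], 2000, seed=0)
        fit = fit_gmm(vals, seed=0)
        assert fit.k == 1

    def test_two_component_recovery(self):
        vals = simulate_ks_mixture([0.18, 0.75], [0.25, 0.25], [0.6, 0.4], 3000, seed=1)
        fit = fit_gmm(vals, seed=0)
        assert fit.k == 2
        assert fit.modes[0] == pytest.approx(0.18, abs=0.03)
        assert fit.modes[1] == pytest.approx(0.75, abs=0.10)

    def test_determinism(self):
        vals = simulate_ks_mixture([0.2, 0.8], [0.2, 0.2], [0.5, 0.5], 1000, seed=2)
        a, b = fit_gmm(vals, seed=3), fit_gmm(vals, seed=3)
        assert a.k == b.k and np.allclose(a.means, b.means)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_gmm([0.1] * 20, k_range=range(1, 6))


class TestWithinOrthogroupCompare:
    def _tables(self, par_mean, ort_mean, n=300, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        ogs = [f"og{i}" for i in range(n)]
        par = pd.DataFrame({
            "orthogroup": ogs,
            "ks": np.exp(np.log(par_mean) + 0.2 * rng.standard_normal(n)),
        })
        ort = pd.DataFrame({
            "orthogroup": ogs,
            "ks": np.exp(np.log(ort_mean) + 0.2 * rng.standard_normal(n)),
        })
        return par, ort

    def test_paralogs_older_detected(self):
        par, ort = self._tables(0.18, 0.10)
        res = within_orthogroup_compare(par, ort)
        assert res.defined and res.direction == "paralogs_older"
        assert res.p_value < 1e-6

    def test_restricted_to_shared_orthogroups(self):
        par, ort = self._tables(0.18, 0.10)
        ort2 = ort[ort["orthogroup"] != "og0"]
        res = within_orthogroup_compare(par, ort2)
        assert res.n_paralog == len(par) - 1

    def test_identical_distributions_high_p_typical(self):
        pvals = []
        for seed in range(30):
            par, ort = self._tables(0.2, 0.2, n=150, seed=seed)
            pvals.append(within_orthogroup_compare(par, ort).p_value)
        assert np.mean([p < 0.05 for p in pvals]) <= 0.2

    def test_empty_class_flagged(self):
        import pandas as pd

        par = pd.DataFrame({"orthogroup": ["og1"], "ks": [0.2]})
        ort = pd.DataFrame({"orthogroup": ["og2"], "ks": [0.1]})
        res = within_orthogroup_compare(par, ort)
        assert not res.defined
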