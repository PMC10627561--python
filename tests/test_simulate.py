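import math

import numpy as np
import pytest
from scipy import stats

from polyconflict.dupmap import lca_reconcile
from polyconflict.quartets import count_quartets
from polyconflict.simulate import (
    DLParams,
    IntrogressionEdge,
    simulate_alignment,
    simulate_codon_pairs,
    simulate_dl_gene_trees,
    simulate_ks_mixture,
    simulate_msc_gene_trees,
    simulate_network_gene_trees,
    simulate_species_tree,
)
from polyconflict.trees import parse_newick, write_newick


class TestSpeciesTree:
    def test_three_taxa_shape(self):
        t = simulate_species_tree(3, seed=0)
        assert t.n_tips() == 3
        assert len(t.internal_nodes()) == 2  # root + one cherry

    def test_determinism(self):
        assert write_newick(simulate_species_tree(9, seed=5)) == write_newick(
            simulate_species_tree(9, seed=5)
        )

    def test_twenty_taxa_positive_lengths(self):
        t = simulate_species_tree(20, seed=1)
        lengths = [n.length for n in t.preorder() if n is not t.root]
        assert len([n for n in t.internal_nodes(exclude_root=True)]) == 18
        assert all(l > 0 for l in lengths)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate_species_tree(2, seed=0)


class TestMscSimulator:
    def test_determinism(self, quartet_species):
        a = simulate_msc_gene_trees(quartet_species, 5, seed=3)
        b = simulate_msc_gene_trees(quartet_species, 5, seed=3)
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]

    def test_star_tree_equal_frequencies(self):
        """Internal branch t=0: the three quartet resolutions are ~1/3 each."""
        sp = parse_newick("((a:1,b:1):0,(c:1,d:1):0);")
        genes = simulate_msc_gene_trees(sp, 3000, seed=2)
        qc = count_quartets(genes, [("a", "b", "c", "d")])[0]
        for c in qc.counts:
            assert abs(c / qc.n - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / qc.n)

    def test_terminal_branch_policy(self):
        sp = parse_newick("((a,b):1,(c,d):0);")  # terminal lengths absent
        genes = simulate_msc_gene_trees(sp, 10, seed=0)
        assert len(genes) == 10

    def test_internal_missing_length_errors(self):
        sp = parse_newick("((a:1,b:1),(c:1,d:1):0);")
        with pytest.raises(ValueError, match="internal"):
            simulate_msc_gene_trees(sp, 5, seed=0)


class TestNetworkSimulator:
    def test_gamma_zero_matches_msc(self, dstat_species):
        """With gamma=0 the topology distribution equals the plain MSC
        (chi-square on qcCF counts at alpha=0.001)."""
        edge = IntrogressionEdge(frozenset({"P3"}), frozenset({"P2"}), 0.5, 0.0)
        net, _ = simulate_network_gene_trees(dstat_species, [edge], 2500, seed=4)
        msc = simulate_msc_gene_trees(dstat_species, 2500, seed=999)
        quad = ("O", "P1", "P2", "P3")
        c_net = np.array(count_quartets(net, [quad])[0].counts)
        c_msc = np.array(count_quartets(msc, [quad])[0].counts)
        expected = (c_net + c_msc) / 2
        chi2 = ((c_net - expected) ** 2 / expected).sum() + (
            (c_msc - expected) ** 2 / expected
        ).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_gamma_monotonicity(self, dstat_species):
        """The P2+P3 resolution frequency increases with gamma."""
        quad = ("O", "P1", "P2", "P3")
        freqs = []
        for gamma in (0.0, 0.25, 0.5, 0.75, 1.0):
            edge = IntrogressionEdge(frozenset({"P3"}), frozenset({"P2"}), 0.5, gamma)
            genes, _ = simulate_network_gene_trees(dstat_species, [edge], 2000, seed=11)
            qc = count_quartets(genes, [quad])[0]
            freqs.append(qc.counts[0] / qc.n)  # O-P1 | P2-P3
        assert all(b > a - 0.02 for a, b in zip(freqs, freqs[1:]))
        assert freqs[-1] > freqs[0] + 0.2

    def test_truth_records_moved_lineages(self, dstat_species):
        edge = IntrogressionEdge(frozenset({"P3"}), frozenset({"P2"}), 0.5, 1.0)
        _, truth = simulate_network_gene_trees(dstat_species, [edge], 50, seed=1)
        assert all(r["introgressed"] for r in truth.records)

    def test_event_time_outside_branch_errors(self, dstat_species):
        edge = IntrogressionEdge(frozenset({"P3"}), frozenset({"P2"}), 5.0, 0.5)
        with pytest.raises(ValueError, match="outside"):
            simulate_network_gene_trees(dstat_species, [edge], 5, seed=0)


class TestDLSimulator:
    def test_zero_rates_reproduce_species_tree(self, caterpillar6):
        genes, truth = simulate_dl_gene_trees(caterpillar6, DLParams(0, 0), 20, seed=0)
        ref = caterpillar6.clade_sets()
        for tree in genes:
            labels = {t.label for t in tree.tips()}
            assert labels == {f"s{i}@1" for i in range(1, 7)}
            stripped = {
                frozenset(l.rsplit("@", 1)[0] for l in clade)
                for clade in tree.clade_sets()
            }
            assert stripped == ref

    def test_wgd_full_retention_single_duplication(self, caterpillar6):
        clade = frozenset({"s1", "s2", "s3"})
        genes, truth = simulate_dl_gene_trees(
            caterpillar6, DLParams(0, 0, clade, 1.0), 10, seed=1
        )
        for tree in genes:
            rec = lca_reconcile(tree, caterpillar6, genes.taxon_map)
            assert rec.n_duplications == 1
            assert rec.duplications == {clade: 1}

    def test_partial_retention_rate(self, caterpillar6):
        """With rates 0 the fraction of trees keeping both WGD copies is r."""
        clade = frozenset({"s1", "s2", "s3"})
        genes, truth = simulate_dl_gene_trees(
            caterpillar6, DLParams(0, 0, clade, 0.3), 400, seed=2
        )
        kept = sum(1 for r in truth.records if r.get("wgd_retained"))
        assert abs(kept / 400 - 0.3) < 3 * math.sqrt(0.3 * 0.7 / 400)
        # retained iff a duplication node exists
        dup_trees = sum(
            1 for t in genes if lca_reconcile(t, caterpillar6, genes.taxon_map).n_duplications
        )
        assert dup_trees == kept

    def test_determinism(self, caterpillar6):
        a, _ = simulate_dl_gene_trees(caterpillar6, DLParams(0.1, 0.1), 10, seed=7)
        b, _ = simulate_dl_gene_trees(caterpillar6, DLParams(0.1, 0.1), 10, seed=7)
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]


class TestAlignmentSimulator:
    def test_zero_lengths_identical_rows(self):
        t = parse_newick("((a:0,b:0):0,c:0);")
        aln = simulate_alignment(t, 200, seed=0)
        assert (aln.data == aln.data[0]).all()

    def test_jc_pairwise_distance(self):
        """Observed mismatch fraction matches (3/4)(1 - e^{-4d/3})."""
        t = parse_newick("(a:0.05,b:0.05);")
        aln = simulate_alignment(t, 100_000, seed=3)
        diff = (aln.row("a") != aln.row("b")).mean()
        expected = 0.75 * (1 - math.exp(-4 * 0.1 / 3))
        assert abs(diff - expected) < 3 * math.sqrt(expected * (1 - expected) / 100_000)

    def test_determinism_and_negative_length(self):
        t = parse_newick("(a:0.1,b:0.1);")
        assert (simulate_alignment(t, 50, seed=1).data == simulate_alignment(t, 50, seed=1).data).all()
        with pytest.raises(ValueError):
            simulate_alignment(t, -1, seed=0)


class TestCodonPairs:
    def test_zero_divergence_identical(self):
        s1, s2, _ = simulate_codon_pairs(0.0, 0.0, 100, seed=0)
        assert s1 == s2

    def test_determinism(self):
        assert simulate_codon_pairs(0.2, 0.1, 100, seed=4) == simulate_codon_pairs(
            0.2, 0.1, 100, seed=4
        )

    def test_no_stop_codons(self):
        from polyconflict.ks import STOP_CODONS

        s1, s2, _ = simulate_codon_pairs(0.5, 0.3, 300, seed=5)
        for seq in (s1, s2):
            assert not any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq), 3))

    def test_saturation_warning(self):
        with pytest.warns(UserWarning, match="saturation"):
            simulate_codon_pairs(5.0, 0.0, 100, seed=0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            simulate_codon_pairs(0.1, 0.0, 10, seed=0)


class TestKsMixture:
    def test_single_component_mean(self):
        vals = simulate_ks_mixture([0.4], [0.1], [1.0], 4000, seed=0)
        se = np.std(np.log(vals)) / math.sqrt(len(vals))
        assert abs(np.mean(np.log(vals)) - math.log(0.4)) < 3 * se

    def test_degenerate_weights(self):
        vals = simulate_ks_mixture([0.2, 2.0], [0.05, 0.05], [1.0, 0.0], 500, seed=1)
        assert vals.max() < 0.5  # all from the first component

    def test_window_truncation(self):
        vals = simulate_ks_mixture([0.05], [1.0], [1.0], 1000, seed=2)
        assert vals.min() >= 0.05 and vals.max() <= 3.0

    def test_inconsistent_lengths(self):
        with pytest.raises(ValueError):
            simulate_ks_mixture([0.1, 0.2], [0.1], [1.0], 10, seed=0)
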