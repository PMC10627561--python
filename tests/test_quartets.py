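import itertools

import dendropy
import numpy as np
import pytest

from polyconflict.quartets import (
    QuartetCounts,
    count_quartets,
    eqp_ic,
    map_rejected_quartets,
    simplex_coordinates,
    species_tree_resolution,
    t1_test,
    t3_test,
)
from polyconflict.simulate import simulate_msc_gene_trees, simulate_species_tree
from polyconflict.trees import parse_newick, write_newick


def _dendropy_quartet(tree_newick: str, quad: tuple[str, ...]) -> int | None:
    """Independent oracle: prune with dendropy, compare to the 3 references."""
    a, b, c, d = quad
    refs = [f"(({a},{b}),({c},{d}));", f"(({a},{c}),({b},{d}));", f"(({a},{d}),({b},{c}));"]
    tns = dendropy.TaxonNamespace()
    t = dendropy.Tree.get(data=tree_newick, schema="newick", taxon_namespace=tns)
    keep = [tx for tx in tns if tx.label in quad]
    if len(keep) < 4:
        return None
    t.retain_taxa(keep)
    t.update_bipartitions(suppress_unifurcations=True)
    for i, ref in enumerate(refs):
        r = dendropy.Tree.get(data=ref, schema="newick", taxon_namespace=tns)
        r.encode_bipartitions()
        if dendropy.calculate.treecompare.symmetric_difference(t, r) == 0:
            return i
    return None


class TestCountQuartets:
    def test_all_concordant(self):
        trees = [parse_newick("((a,b),(c,d));")] * 3
        qc = count_quartets(trees, [("a", "b", "c", "d")])[0]
        assert qc.counts == (3, 0, 0)

    def test_missing_taxon_contributes_nothing(self):
        trees = [parse_newick("((a,b),c);")]
        qc = count_quartets(trees, [("a", "b", "c", "d")])[0]
        assert qc.n == 0

    def test_invalid_quadruple(self):
        with pytest.raises(ValueError):
            count_quartets([parse_newick("((a,b),(c,d));")], [("a", "a", "b", "c")])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dendropy_pruning_oracle(self, seed):
        """Counts equal per-tree induced-quartet enumeration via dendropy."""
        sp = simulate_species_tree(6, seed=seed + 50)
        genes = simulate_msc_gene_trees(sp, 10, seed=seed)
        taxa = sorted(sp.tip_labels)
        quads = list(itertools.combinations(taxa, 4))
        ours = count_quartets(genes, quads)
        for qc in ours:
            expected = [0, 0, 0]
            for t in genes:
                r = _dendropy_quartet(write_newick(t), qc.quadruple)
                if r is not None:
                    expected[r] += 1
            assert list(qc.counts) == expected


class TestT3:
    def test_star_fit(self):
        r = t3_test(QuartetCounts(("a", "b", "c", "d"), (100, 100, 100)))
        assert r.mu_hat == pytest.approx(1 / 3)
        assert r.lrt == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_tree_fit(self):
        r = t3_test(QuartetCounts(("a", "b", "c", "d"), (300, 0, 0)))
        assert r.mu_hat == 0.0 and r.lrt == 0.0 and r.p_value == pytest.approx(1.0)

    def test_skewed_minors_rejected(self):
        """Hand-evaluated LRT for counts (150, 140, 10)."""
        r = t3_test(QuartetCounts(("a", "b", "c", "d"), (150, 140, 10)), alpha=0.01, seed=1)
        expected_lrt = 2 * (140 * np.log(140 / 75) + 10 * np.log(10 / 75))
        assert r.mu_hat == pytest.approx(0.25)
        assert r.lrt == pytest.approx(expected_lrt, rel=1e-9)
        assert r.rejected

    def test_minor_count_permutation_invariance(self):
        a = t3_test(QuartetCounts(("a", "b", "c", "d"), (150, 140, 10)), seed=3)
        b = t3_test(QuartetCounts(("a", "b", "c", "d"), (150, 10, 140)), seed=3)
        assert a.p_value == b.p_value and a.lrt == b.lrt

    def test_zero_counts_flagged(self):
        r = t3_test(QuartetCounts(("a", "b", "c", "d"), (0, 0, 0)))
        assert np.isnan(r.p_value)

    def test_bootstrap_agrees_with_chisq_roughly(self):
        counts = QuartetCounts(("a", "b", "c", "d"), (220, 90, 55))
        pb = t3_test(counts, B=4000, seed=0).p_value
        pc = t3_test(counts, pvalue_method="chisq1").p_value
        assert (pb < 0.05) == (pc < 0.05)


class TestT1:
    def test_concordant_with_species_tree(self):
        r = t1_test(QuartetCounts(("a", "b", "c", "d"), (90, 5, 5)), 0, seed=0)
        assert r.p_value > 0.05

    def test_discordant_modal_rejected(self):
        r = t1_test(QuartetCounts(("a", "b", "c", "d"), (5, 90, 5)), 0, alpha=0.01, seed=0)
        assert r.rejected

    def test_pure_concordant_p_one(self):
        r = t1_test(QuartetCounts(("a", "b", "c", "d"), (200, 0, 0)), 0)
        assert r.p_value == pytest.approx(1.0)

    def test_bad_resolution_index(self):
        with pytest.raises(ValueError):
            t1_test(QuartetCounts(("a", "b", "c", "d"), (1, 1, 1)), 5)


class TestSimplex:
    def test_examples(self):
        assert simplex_coordinates(QuartetCounts(("a", "b", "c", "d"), (50, 30, 20))) == (
            0.5, 0.3, 0.2,
        )
        centroid = simplex_coordinates(QuartetCounts(("a", "b", "c", "d"), (1, 1, 1)))
        assert centroid == pytest.approx((1 / 3,) * 3)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = tuple(int(x) for x in rng.integers(0, 50, 3))
            if sum(c) == 0:
                continue
            assert sum(simplex_coordinates(QuartetCounts(("a", "b", "c", "d"), c))) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            simplex_coordinates(QuartetCounts(("a", "b", "c", "d"), (0, 0, 0)))


class TestMapRejected:
    def test_single_edge_path(self, caterpillar6):
        # (s1,s2,s3,s4): the induced quartet's internal path is exactly the
        # edge above the {s1,s2} cherry (keyed by its canonical side)
        counts = map_rejected_quartets(caterpillar6, [("s1", "s2", "s3", "s4")])
        hit = {tuple(sorted(k)) for k, v in counts.items() if v == 1}
        assert hit == {("s3", "s4", "s5", "s6")}
        assert sum(counts.values()) == 1

    def test_two_edge_path(self, caterpillar6):
        # (s1,s2,s4,s5): both the {s1,s2} edge and the {s1,s2,s3} edge split
        # the quadruple 2|2, so both lie on the induced internal path
        counts = map_rejected_quartets(caterpillar6, [("s1", "s2", "s4", "s5")])
        hit = {tuple(sorted(k)) for k, v in counts.items() if v == 1}
        assert hit == {("s3", "s4", "s5", "s6"), ("s4", "s5", "s6")}
        assert sum(counts.values()) == 2

    def test_empty_rejected(self, caterpillar6):
        counts = map_rejected_quartets(caterpillar6, [])
        assert all(v == 0 for v in counts.values())

    def test_unknown_taxon(self, caterpillar6):
        with pytest.raises(KeyError):
            map_rejected_quartets(caterpillar6, [("s1", "s2", "s3", "zz")])

    def test_relabeling_equivariance(self, caterpillar6):
        counts = map_rejected_quartets(caterpillar6, [("s1", "s3", "s4", "s6")])
        relabeled = parse_newick(
            write_newick(caterpillar6).replace("s1", "t1").replace("s3", "t3")
        )
        counts2 = map_rejected_quartets(relabeled, [("t1", "t3", "s4", "s6")])
        key = lambda k: tuple(sorted(x.replace("t", "s") for x in k))
        assert {key(k): v for k, v in counts.items()} == {key(k): v for k, v in counts2.items()}


class TestEqpIc:
    def test_identical_trees_score_one(self, caterpillar6):
        genes = [caterpillar6.copy() for _ in range(10)]
        scores = eqp_ic(caterpillar6, genes)
        assert scores and all(v == pytest.approx(1.0) for v in scores.values())

    def test_dominant_alternative_negative(self):
        species = parse_newick("(((a,b),(c,d)),(e,f));")
        alt = parse_newick("(((a,c),(b,d)),(e,f));")
        scores = eqp_ic(species, [alt] * 10)
        conflicted = [
            k for k in scores if set(k) in ({"a", "b"}, {"c", "d", "e", "f"},
                                            {"c", "d"}, {"a", "b", "e", "f"})
        ]
        assert conflicted and all(scores[k] < 0 for k in conflicted)

    def test_species_resolution_lookup(self, caterpillar6):
        assert species_tree_resolution(caterpillar6, ("s1", "s2", "s3", "s4")) == 0

    def test_monotone_in_concordant_fraction(self):
        """Score increases as the reference resolution's frequency grows,
        holding the two alternatives balanced."""
        species = parse_newick("(((a,b),(c,d)),(e,f));")
        alt1 = parse_newick("(((a,c),(b,d)),(e,f));")
        alt2 = parse_newick("(((a,d),(b,c)),(e,f));")
        edge = frozenset({"a", "b"})
        scores = []
        for k in range(0, 11, 2):
            genes = [species.copy()] * k + [alt1.copy()] * ((10 - k) // 2) \
                + [alt2.copy()] * ((10 - k) // 2)
            s = eqp_ic(species, genes)
            key = next(kk for kk in s if set(kk) in ({"a", "b"}, {"c", "d", "e", "f"}))
            scores.append(s[key])
        assert scores == sorted(scores)
        assert scores[0] < 0 < scores[-1] == pytest.approx(1.0)
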