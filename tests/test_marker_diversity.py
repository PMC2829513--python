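import math

import dendropy
import numpy as np
import pytest

from ssrmine.marker_diversity import (
    DistanceMatrix,
    GenotypeTable,
    allele_frequencies,
    bootstrap_nj,
    dps_distance,
    dps_matrix,
    expected_heterozygosity,
    locus_stats,
    neighbor_joining,
    observed_heterozygosity,
    pic,
    pool_individuals,
    read_genotype_tsv,
    write_genotype_tsv,
    write_newick,
    write_phylip,
)


def table_from(calls):
    inds = tuple(calls)
    loci = tuple(next(iter(calls.values())))
    return GenotypeTable(inds, loci, calls)


# ---------------------------------------------------------------------------
# random additive trees as an oracle for NJ


def random_additive_tree(n_taxa, rng):
    """Random binary topology with positive lengths; returns the exact
    leaf-to-leaf path-length matrix computed by its own traversal."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start each taxon as a cluster of {leaf: depth}
    clusters = [{lab: 0.0} for lab in labels]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        a = {k: v + li for k, v in clusters[i].items()}
        b = {k: v + lj for k, v in clusters[j].items()}
        for x, dx in a.items():
            for y, dy in b.items():
                dist[frozenset((x, y))] = dx + dy
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append({**a, **b})
    m = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            m[x, y] = m[y, x] = dist[frozenset((labels[x], labels[y]))]
    return DistanceMatrix(tuple(labels), m)


class TestPerLocusStats:
    def test_allele_frequencies_direct(self):
        t = table_from({"i1": {"L": (100, 102)}, "i2": {"L": (100, 100)}})
        assert allele_frequencies(t, "L") == {100: 0.75, 102: 0.25}

    def test_monomorphic_frequencies(self):
        calls = {f"i{k}": {"L": (98, 98)} for k in range(5)}
        assert allele_frequencies(table_from(calls), "L") == {98: 1.0}

    def test_frequencies_match_gene_copy_tally(self, rng):
        sizes = [100, 102, 104, 106]
        calls = {}
        for k in range(50):
            pair = tuple(sorted(rng.choice(sizes, size=2)))
            calls[f"i{k}"] = {"L": (int(pair[0]), int(pair[1]))}
        t = table_from(calls)
        freqs = allele_frequencies(t, "L")
        tally = {}
        for c in calls.values():
            for a in c["L"]:
                tally[a] = tally.get(a, 0) + 1
        for allele, f in freqs.items():
            assert f == tally[allele] / 100

    def test_observed_heterozygosity(self):
        t = table_from(
            {"i1": {"L": (100, 102)}, "i2": {"L": (100, 100)}, "i3": {"L": (102, 102)}}
        )
        assert observed_heterozygosity(t, "L") == pytest.approx(1 / 3)

    def test_expected_heterozygosity_hand_values(self):
        one_het = table_from({"i1": {"L": (100, 102)}, "i2": {"L": None}})
        assert expected_heterozygosity(one_het, "L") == pytest.approx(1.0)
        two_het = table_from({"i1": {"L": (100, 102)}, "i2": {"L": (100, 102)}})
        assert expected_heterozygosity(two_het, "L") == pytest.approx(2 / 3)

    def test_monomorphic_locus_all_zero(self):
        t = table_from({"i1": {"L": (98, 98)}, "i2": {"L": (98, 98)}})
        s = locus_stats(t, "L")
        assert (s.ho, s.he, s.pic) == (0.0, 0.0, 0.0)
        assert s.na == 1

    def test_pic_hand_value_and_monotonicity(self):
        t = table_from({"i1": {"L": (100, 102)}, "i2": {"L": (100, 102)}})
        assert pic(t, "L") == pytest.approx(0.375)
        # k equifrequent alleles: PIC strictly increases with k
        def pic_equifreq(k):
            p = 1.0 / k
            return 1 - k * p * p - 2 * (k * (k - 1) / 2) * p ** 4
        values = [pic_equifreq(k) for k in range(2, 11)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_pic_bounds_vs_plugin_heterozygosity(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            sizes = (100 + 2 * np.arange(k)).tolist()
            calls = {}
            for i in range(30):
                pair = tuple(sorted(rng.choice(sizes, size=2)))
                calls[f"i{i}"] = {"L": (int(pair[0]), int(pair[1]))}
            t = table_from(calls)
            freqs = allele_frequencies(t, "L")
            he_plug = 1 - sum(p * p for p in freqs.values())
            assert 0 <= pic(t, "L") <= he_plug
            if len(freqs) > 1:
                assert pic(t, "L") < he_plug
                assert expected_heterozygosity(t, "L") >= he_plug

    def test_all_missing_locus_rejected(self):
        t = table_from({"i1": {"L": None}, "i2": {"L": None}})
        with pytest.raises(ValueError):
            allele_frequencies(t, "L")


class TestDps:
    def test_identical_genotypes_distance_zero(self):
        t = table_from(
            {"i1": {"L1": (1, 2), "L2": (3, 3)}, "i2": {"L1": (1, 2), "L2": (3, 3)}}
        )
        assert dps_distance(t, "i1", "i2") == 0.0

    def test_half_shared_gives_ln2(self):
        t = table_from(
            {
                "i1": {"L1": (100, 102), "L2": (200, 202)},
                "i2": {"L1": (100, 104), "L2": (200, 204)},
            }
        )
        assert dps_distance(t, "i1", "i2") == pytest.approx(math.log(2))

    def test_symmetry_on_random_tables(self, rng):
        sizes = [100, 102, 104]
        calls = {}
        for i in range(8):
            row = {}
            for loc in ("L1", "L2", "L3"):
                if rng.random() < 0.2:
                    row[loc] = None
                else:
                    pair = tuple(sorted(rng.choice(sizes, size=2)))
                    row[loc] = (int(pair[0]), int(pair[1]))
            calls[f"i{i}"] = row
        t = GenotypeTable(tuple(calls), ("L1", "L2", "L3"), calls)
        inds = t.individuals
        for a in inds:
            for b in inds:
                if any(
                    t.calls[a][l] is not None and t.calls[b][l] is not None
                    for l in t.loci
                ):
                    assert dps_distance(t, a, b) == dps_distance(t, b, a)
                    assert dps_distance(t, a, b) >= 0

    def test_nothing_shared_is_finite_flooring(self):
        t = table_from({"i1": {"L1": (1, 1)}, "i2": {"L1": (9, 9)}})
        d = dps_distance(t, "i1", "i2")
        assert d == pytest.approx(-math.log(0.5 / 2))

    def test_no_common_locus_rejected(self):
        t = table_from({"i1": {"L1": (1, 1), "L2": None},
                        "i2": {"L1": None, "L2": (2, 2)}})
        with pytest.raises(ValueError):
            dps_distance(t, "i1", "i2")


class TestNeighborJoining:
    def test_four_taxon_additive_topology_and_lengths(self):
        m = np.array(
            [[0, 2, 4, 5], [2, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]], float
        )
        dm = DistanceMatrix(("A", "B", "C", "D"), m)
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        pm = tree.path_length_matrix()
        assert np.abs(pm.values - m).max() < 1e-12

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = neighbor_joining(dm)
        newick = write_newick(tree)
        assert newick == "(A:0.50000,B:0.50000);"

    def test_additivity_recovery_on_random_trees(self, rng):
        for _ in range(10):
            dm = random_additive_tree(6, rng)
            tree = neighbor_joining(dm)
            pm = tree.path_length_matrix()
            order = [pm.labels.index(l) for l in dm.labels]
            recovered = pm.values[np.ix_(order, order)]
            assert np.abs(recovered - dm.values).max() <= 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestBootstrap:
    def _table(self, rng, n_loci=5, n_ind=8):
        sizes = [100, 102, 104, 106]
        calls = {}
        for i in range(n_ind):
            row = {}
            for j in range(n_loci):
                pair = tuple(sorted(rng.choice(sizes, size=2)))
                row[f"L{j}"] = (int(pair[0]), int(pair[1]))
            calls[f"i{i}"] = row
        return GenotypeTable(tuple(calls), tuple(f"L{j}" for j in range(n_loci)), calls)

    def test_zero_replicates_no_supports(self, rng):
        t = self._table(rng)
        tree = bootstrap_nj(t, 0, seed=1)
        def supports(node):
            out = [] if node.support is None else [node.support]
            for c in node.children:
                out += supports(c)
            return out
        assert supports(tree.root) == []

    def test_same_seed_reproducible(self, rng):
        t = self._table(rng)
        t1 = bootstrap_nj(t, 25, seed=42)
        t2 = bootstrap_nj(t, 25, seed=42)
        assert write_newick(t1) == write_newick(t2)

    def test_identical_loci_give_full_support(self, rng):
        base = self._table(rng, n_loci=1)
        calls = {
            ind: {f"L{j}": base.calls[ind]["L0"] for j in range(4)}
            for ind in base.individuals
        }
        t = GenotypeTable(base.individuals, tuple(f"L{j}" for j in range(4)), calls)
        tree = bootstrap_nj(t, 20, seed=3)
        def supports(node):
            out = [] if node.support is None else [node.support]
            for c in node.children:
                out += supports(c)
            return out
        sup = supports(tree.root)
        assert sup and all(s == 100.0 for s in sup)

    def test_negative_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_nj(self._table(rng), -1, seed=0)


class TestSerialization:
    def test_newick_roundtrip_against_dendropy(self, rng):
        dm = random_additive_tree(7, rng)
        tree = neighbor_joining(dm)
        newick = write_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        own = tree.path_length_matrix()
        for i, a in enumerate(own.labels):
            for j, b in enumerate(own.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        own.values[i, j], abs=1e-4  # limited by 5-decimal output
                    )

    def test_newick_support_threshold_suppression(self, rng):
        t = TestBootstrap()._table(rng, n_loci=6, n_ind=10)
        tree = bootstrap_nj(t, 20, seed=5)
        full = write_newick(tree)
        pruned = write_newick(tree, min_support=101)  # suppress everything
        assert ")" in pruned
        import re as _re
        assert not _re.search(r"\)\d", pruned)
        assert len(full) >= len(pruned)

    def test_phylip_square_format(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.5], [1.5, 0.0]]))
        text = write_phylip(dm)
        lines = text.strip().split("\n")
        assert lines[0].strip() == "2"
        assert lines[1].startswith("A".ljust(10))
        assert "1.500000" in lines[1]

    def test_genotype_tsv_roundtrip(self, tmp_path, toy_genotypes):
        p = tmp_path / "geno.tsv"
        write_genotype_tsv(toy_genotypes, p)
        back = read_genotype_tsv(p)
        assert back == toy_genotypes

    def test_bad_genotype_cell_rejected(self, tmp_path):
        p = tmp_path / "geno.tsv"
        p.write_text("individual\tL1\ni1\t100-102\ni2\t100/102\n")
        with pytest.raises(ValueError, match="bad genotype cell"):
            read_genotype_tsv(p)


def test_pool_individuals_keeps_first_nonmissing(toy_genotypes):
    pooled = pool_individuals(toy_genotypes, {"i1": "sp1", "i2": "sp1", "i3": "sp2"})
    assert pooled.individuals == ("sp1", "sp2")
    assert pooled.calls["sp1"]["L1"] == (100, 102)
    assert pooled.calls["sp2"]["L2"] is None
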