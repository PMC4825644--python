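import math

import numpy as np
import pytest

from radmap.phylo import (
    DistanceMatrix,
    PhyloTree,
    TagMatrix,
    bootstrap_support,
    concatenate_snps,
    k2p_distance,
    nj_tree,
    presence_distance,
    strain_consensus_tags,
)


# ---------------------------------------------------------------------------
# strain consensus filtering
# ---------------------------------------------------------------------------

class TestStrainConsensus:
    def _table(self, rows):
        return np.array(rows)

    def test_missing_threshold_is_inclusive(self):
        # strain of 6 individuals, threshold 3: a tag absent in 3 is discarded
        table = self._table([[0], [0], [0], [1], [1], [1]])
        tm = strain_consensus_tags(table, ["S"] * 6, ["t1"], {"S": 3})
        assert tm.tags == []
        tm2 = strain_consensus_tags(
            self._table([[0], [0], [1], [1], [1], [1]]), ["S"] * 6, ["t1"], {"S": 3}
        )
        assert tm2.tags == ["t1"]

    def test_hom_everywhere_retained_for_all_strains(self):
        table = self._table([[1], [1], [1], [1]])
        tm = strain_consensus_tags(table, ["A", "A", "B", "B"], ["t1"], {"A": 1, "B": 1})
        assert tm.present.all()

    def test_het_in_one_individual_discards_for_that_strain(self):
        # one heterozygous individual poisons the tag for strain A only
        table = self._table([[-1], [1], [1], [1]])
        tm = strain_consensus_tags(table, ["A", "A", "B", "B"], ["t1"], {"A": 2, "B": 2})
        assert tm.tags == ["t1"]
        byt = dict(zip(tm.taxa, tm.present[:, 0]))
        assert not byt["A"] and byt["B"]

    def test_within_strain_polymorphism_discards(self):
        # two different homozygous alleles within a strain
        table = self._table([[1], [2]])
        tm = strain_consensus_tags(table, ["A", "A"], ["t1"], {"A": 2})
        assert tm.tags == []

    def test_unknown_strain_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="threshold"):
            strain_consensus_tags(self._table([[1]]), ["A"], ["t1"], {})


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestPresenceDistance:
    def test_identical_rows_are_zero(self):
        tm = TagMatrix(taxa=["A", "B"], tags=["t1", "t2"], present=np.ones((2, 2), bool))
        assert presence_distance(tm).d[0, 1] == 0

    def test_disjoint_tag_sets(self):
        present = np.array([[1, 1, 1, 0, 0], [0, 0, 0, 1, 1]], bool)
        tm = TagMatrix(taxa=["A", "B"], tags=[f"t{i}" for i in range(5)], present=present)
        assert presence_distance(tm).d[0, 1] == 5

    def test_single_difference(self):
        present = np.array([[1, 1], [1, 0]], bool)
        tm = TagMatrix(taxa=["A", "B"], tags=["t1", "t2"], present=present)
        assert presence_distance(tm).d[0, 1] == 1

    def test_metric_properties_on_random_instances(self):
        rng = np.random.default_rng(17)
        present = rng.random((5, 300)) < 0.7
        present[:, 0] = True  # keep no tag all-absent
        tm = TagMatrix(taxa=list("ABCDE"), tags=[f"t{i}" for i in range(300)], present=present)
        d = presence_distance(tm).d
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestK2P:
    def test_identical_sequences(self):
        d = k2p_distance({"A": "ACGTACGT", "B": "ACGTACGT"})
        assert d.d[0, 1] == 0

    def test_closed_form_value(self):
        # 20 sites: 2 transitions (P=0.1), 1 transversion (Q=0.05)
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        d = k2p_distance({"x": a, "y": b})
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert d.d[0, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_raises_naming_pair(self):
        a = "A" * 10
        b = "C" * 5 + "T" * 5  # Q = 1
        with pytest.raises(ValueError, match="'x'.*'y'|'y'.*'x'"):
            k2p_distance({"x": a, "y": b})

    def test_ambiguous_sites_excluded_pairwise(self):
        d = k2p_distance({"A": "ACGTN", "B": "ACGTA"})
        assert d.d[0, 1] == 0


class TestConcatenateSnps:
    def test_polymorphic_columns_collected_in_tag_order(self):
        tags = {
            "A": {"t1": "ACGT", "t2": "ACC"},
            "B": {"t1": "ACGA", "t2": "ATC"},
            "C": {"t1": "CCGA", "t2": "ACC"},
        }
        aln = concatenate_snps(tags)
        assert {len(s) for s in aln.values()} == {3}
        assert aln["A"] == "AT" + "C"
        assert aln["C"] == "CA" + "C"

    def test_no_polymorphic_columns_warns_and_is_empty(self):
        tags = {"A": {"t1": "ACG"}, "B": {"t1": "ACG"}}
        with pytest.warns(UserWarning, match="no polymorphic"):
            aln = concatenate_snps(tags)
        assert aln == {"A": "", "B": ""}

    def test_site_count_matches_independent_recount(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        taxa = ["A", "B", "C"]
        tags = {t: {} for t in taxa}
        for k in range(20):
            for t in taxa:
                tags[t][f"t{k:02d}"] = "".join(rng.choice(bases, size=10))
        aln = concatenate_snps(tags)
        expected = 0
        for k in sorted(tags["A"]):
            for col in range(10):
                if len({tags[t][k][col] for t in taxa}) >= 2:
                    expected += 1
        assert len(aln["A"]) == expected

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="lengths differ"):
            concatenate_snps({"A": {"t1": "ACG"}, "B": {"t1": "AC"}})


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def _additive_4taxon():
    # unrooted tree: A-1-x, B-2-x, x-1-y, C-3-y, D-4-y
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        float,
    )
    return DistanceMatrix(taxa=taxa, d=d)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        tree = nj_tree(_additive_4taxon())
        assert tree.splits() == {frozenset({"C", "D"})}
        recovered = tree.path_lengths()
        np.testing.assert_allclose(
            recovered.d, _additive_4taxon().d[np.ix_([0, 1, 2, 3], [0, 1, 2, 3])], atol=1e-9
        )

    def test_identical_rows_make_zero_cherry(self):
        d = np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(taxa=["A", "B", "C"], d=d))
        pl = tree.path_lengths()
        assert pl.d[pl.taxa.index("A"), pl.taxa.index("B")] == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["A", "B"], d=np.zeros((2, 2))))

    def test_topology_agrees_with_dendropy_on_additive_matrix(self):
        """Independent oracle: dendropy's NJ on the same additive matrix."""
        import dendropy

        dm = _additive_4taxon()
        csv = "," + ",".join(dm.taxa) + "\n" + "\n".join(
            t + "," + ",".join(str(v) for v in row) for t, row in zip(dm.taxa, dm.d)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        labels = {
            frozenset(
                taxon.label
                for taxon in edge.bipartition.leafset_taxa(dtree.taxon_namespace)
            )
            for edge in dtree.bipartition_edge_map.values()
        }
        assert frozenset({"C", "D"}) in labels or frozenset({"A", "B"}) in labels

    def test_recovers_simulated_tag_topology(self):
        from radmap.simulate import simulate_tag_evolution

        newick = "((DANlike:1,VOLlike:1):2,(PANlike:1,HYlike:1):2,KCOUT:4);"
        tm = simulate_tag_evolution(newick, n_root_tags=3000, loss_rate_per_unit=0.05, seed=5)
        tree = nj_tree(presence_distance(tm))
        assert tree.has_split({"DANlike", "VOLlike"})
        assert tree.has_split({"HYlike", "PANlike"})


class TestBootstrap:
    def _builder(self):
        return lambda data: nj_tree(presence_distance(data))

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(3)
        present = rng.random((5, 60)) < 0.8
        present[:, 0] = True
        tm = TagMatrix(taxa=list("ABCDE"), tags=[f"t{i}" for i in range(60)], present=present)
        tree = bootstrap_support(tm, self._builder(), B=1, seed=0)
        sup = []
        def collect(node):
            if node.support is not None:
                sup.append(node.support)
            for c in node.children:
                collect(c)
        collect(tree.root)
        assert sup and all(s in (0.0, 100.0) for s in sup)

    def test_supports_invariant_to_taxon_input_order(self):
        rng = np.random.default_rng(4)
        present = rng.random((5, 80)) < 0.8
        present[:, 0] = True
        taxa = list("ABCDE")
        tags = [f"t{i}" for i in range(80)]
        tm1 = TagMatrix(taxa=taxa, tags=tags, present=present)
        perm = [4, 2, 0, 1, 3]
        tm2 = TagMatrix(taxa=[taxa[i] for i in perm], tags=tags, present=present[perm])
        t1 = bootstrap_support(tm1, self._builder(), B=50, seed=9)
        t2 = bootstrap_support(tm2, self._builder(), B=50, seed=9)

        def supports(tree):
            all_taxa = frozenset(tree.taxa)
            ref = min(all_taxa)
            out = {}

            def walk(node):
                if node.support is not None:
                    names = frozenset(lf.name for lf in node.leaves())
                    side = names if ref not in names else all_taxa - names
                    out[side] = node.support
                for c in node.children:
                    walk(c)

            walk(tree.root)
            return out

        assert supports(t1) == supports(t2)

    def test_newick_carries_supports(self):
        tree = nj_tree(_additive_4taxon())
        tree.attach_supports({frozenset({"C", "D"}): 97.0})
        nwk = tree.to_newick()
        assert ")97:" in nwk and nwk.endswith(";")
        # and parses back with the same leaf set
        back = PhyloTree.from_newick(nwk)
        assert back.taxa == ["A", "B", "C", "D"]
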