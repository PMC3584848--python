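import math
from fractions import Fraction

import numpy as np
import pytest

from protofam import (
    GuideTree,
    UNDEFINED,
    UNMAPPED,
    amplification_ratio,
    amplification_table,
    build_guide_tree,
    find_paralogs,
    gen_guide_case,
    taxonomy_balance,
    taxonomy_balance_table,
    tree_score,
    ts_summary,
)
from protofam.cluster_tree import EXCLUDED
from protofam.mapping import MappingResult, ProteinMapping

from oracles import exhaustive_tree_score


def result_from(assignments):
    return MappingResult({a.protein_id: a for a in assignments}, {})


def random_guide_tree(rng, n, p_interest=0.4):
    """Random topology via UPGMA on random distances, random species labels."""
    d = rng.uniform(0.1, 2.0, size=(n, n))
    d = np.triu(d, 1) + np.triu(d, 1).T
    labels = [f"L{i}" for i in range(n)]
    species = {
        lab: ("interest" if rng.random() < p_interest else "other") for lab in labels
    }
    if not any(v == "interest" for v in species.values()):
        species[labels[0]] = "interest"
    return build_guide_tree(d, labels, species=species)


class TestFindParalogs:
    def mapping(self):
        assignments = []
        # cluster 1: 1 protein; cluster 2: 3 proteins; cluster 3: 12 proteins
        assignments.append(ProteinMapping("s0", 1, 0.1, 10))
        assignments += [ProteinMapping(f"t{i}", 2, 0.1, 10) for i in range(3)]
        assignments += [ProteinMapping(f"u{i}", 3, 0.1, 11) for i in range(12)]
        assignments.append(ProteinMapping("un", UNMAPPED, float("nan"), None))
        return result_from(assignments)

    def test_default_threshold_is_two(self):
        report = find_paralogs(self.mapping(), "map")
        assert report.clusters == [(3, 12), (2, 3)]
        assert report.min_count == 2

    def test_singleton_occupancy_excluded(self):
        report = find_paralogs(self.mapping(), "map")
        assert 1 not in dict((c, n) for c, n in report.clusters)

    def test_buckets(self):
        report = find_paralogs(self.mapping(), "map")
        assert report.buckets == {">=2": 2, ">=10": 1, ">20": 0}

    def test_root_level_aggregates(self):
        report = find_paralogs(self.mapping(), "root")
        assert report.clusters == [(11, 12), (10, 4)]


class TestGuideTree:
    def test_two_leaves_form_a_cherry(self):
        t = build_guide_tree(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        root = t.node(t.root_id)
        assert {t.node(c).name for c in root.children} == {"a", "b"}

    def test_ultrametric_four_taxa_topology(self):
        # ((a,b),(c,d)): within-pair distances 2 and 4, across 10
        d = np.array(
            [
                [0, 2, 10, 10],
                [2, 0, 10, 10],
                [10, 10, 0, 4],
                [10, 10, 4, 0],
            ],
            dtype=float,
        )
        t = build_guide_tree(d, ["a", "b", "c", "d"])
        ab = t.lca([0, 1])
        cd = t.lca([2, 3])
        assert t.subtree_leaf_count(ab) == 2
        assert t.subtree_leaf_count(cd) == 2
        assert t.node(ab).parent == t.node(cd).parent == t.root_id

    def test_equal_distances_tie_break(self):
        t = build_guide_tree(np.where(np.eye(4, dtype=bool), 0.0, 1.0), list("abcd"))
        # deterministic pairing: (a,b) then (c,d), then the two cherries
        ab, cd = t.lca([0, 1]), t.lca([2, 3])
        assert t.subtree_leaf_count(ab) == t.subtree_leaf_count(cd) == 2

    def test_validation(self):
        with pytest.raises(ValueError):
            build_guide_tree(np.zeros((1, 1)), ["a"])
        with pytest.raises(ValueError, match="symmetric"):
            build_guide_tree(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])

    def test_newick_roundtrip(self, rng):
        t = random_guide_tree(rng, 8)
        species = {leaf.name: leaf.species for leaf in t.leaves()}
        back = GuideTree.from_newick(t.to_newick(), species=species)
        assert {l.name for l in back.leaves()} == {l.name for l in t.leaves()}
        assert tree_score(back, "interest").ts == tree_score(t, "interest").ts


class TestTreeScore:
    def test_all_leaves_of_interest(self, rng):
        t = random_guide_tree(rng, 6, p_interest=1.1)
        assert tree_score(t, "interest").ts == 1.0

    def test_single_leaf_is_its_own_subtree(self):
        t, _ = gen_guide_case(1, 7, intermix=True, seed=0)
        assert tree_score(t, "interest").ts == 1.0

    def test_three_of_nine_intermixed(self):
        t, expected = gen_guide_case(3, 6, intermix=True, seed=1)
        res = tree_score(t, "interest")
        assert res.ts == pytest.approx(1 / 3)
        assert (res.d_count, res.min_subtree_leaves) == (3, 9)
        assert expected == pytest.approx(1 / 3)

    def test_absent_species_errors(self, rng):
        t = random_guide_tree(rng, 5)
        with pytest.raises(ValueError, match="absent"):
            tree_score(t, "no-such-species")

    def test_matches_exhaustive_clade_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 13))
            t = random_guide_tree(rng, n)
            res = tree_score(t, "interest")
            assert 0.0 < res.ts <= 1.0
            assert res.ts == exhaustive_tree_score(t, "interest")

    def test_one_iff_species_forms_a_clade(self, rng):
        for seed in range(10):
            t, _ = gen_guide_case(4, 6, intermix=False, seed=seed)
            assert tree_score(t, "interest").ts == 1.0
            t, _ = gen_guide_case(4, 6, intermix=True, seed=seed)
            assert tree_score(t, "interest").ts < 1.0

    def test_summary_degenerate_and_strata(self):
        summary = ts_summary([(2, 1.0), (5, 1.0), (12, 1.0)])
        assert summary["strata"]["2"][-1] == 1
        assert summary["strata"]["3-9"][-1] == 1
        assert summary["strata"][">=10"][-1] == 1
        assert summary["fraction_high_divergence"] == 0.0
        mixed = ts_summary([(2, 0.15), (3, 0.95)])
        assert mixed["fraction_high_divergence"] == 0.5


class TestTaxonomyBalance:
    def test_symmetric_counts(self):
        r = taxonomy_balance(7, 7)
        assert float(r.tb) == 1.0 and r.log2_tb == 0.0

    def test_extreme_amplification(self):
        r = taxonomy_balance(20, 1)
        assert float(r.tb) == 20.0
        assert r.tb >= 10  # clears the high-extreme filter

    def test_undefined_when_one_side_absent(self):
        assert taxonomy_balance(0, 5) is UNDEFINED
        assert taxonomy_balance(5, 0) is UNDEFINED

    def test_inversion_identity_is_exact(self, rng):
        for _ in range(200):
            a, b = int(rng.integers(1, 400)), int(rng.integers(1, 400))
            assert taxonomy_balance(a, b).tb * taxonomy_balance(b, a).tb == 1

    def test_table_extremes_and_shared_roots(self):
        mappings = {
            "A": result_from(
                [ProteinMapping(f"a{i}", 1, 0.1, 100) for i in range(20)]
                + [ProteinMapping("a20", 2, 0.1, 200)]
                + [ProteinMapping("a21", 3, 0.1, 300)]
            ),
            "B": result_from(
                [ProteinMapping("b0", 1, 0.1, 100)]
                + [ProteinMapping(f"b{i}", 2, 0.1, 200) for i in range(1, 12)]
            ),
        }
        out = taxonomy_balance_table(mappings, "A", "B")
        assert out["n_shared_roots"] == 2  # root 300 has no B proteins
        assert out["high_extremes"] == [100]
        assert out["low_extremes"] == [200]


class TestAmplificationRatio:
    @pytest.mark.parametrize(
        "n_prot,n_clusters,expected",
        [(498, 364, 1.37), (279, 155, 1.80), (169, 5, 33.80), (114, 2, 57.00)],
    )
    def test_published_pairs(self, n_prot, n_clusters, expected):
        assert amplification_ratio(n_prot, n_clusters) == expected

    def test_half_up_rounding(self):
        assert amplification_ratio(5, 4) == 1.25
        assert amplification_ratio(249, 200) == 1.25  # 1.245 rounds up

    def test_errors(self):
        with pytest.raises(ValueError):
            amplification_ratio(5, 0)
        with pytest.raises(ValueError):
            amplification_ratio(3, 5)

    def test_table_from_mapping_sorted_and_bounded(self):
        assignments = [ProteinMapping(f"p{i}", 1 + i % 3, 0.1, 10) for i in range(9)]
        assignments += [ProteinMapping(f"q{i}", 7, 0.1, 20) for i in range(4)]
        assignments += [ProteinMapping("x", UNMAPPED, float("nan"), None)]
        assignments += [ProteinMapping("y", 9, 0.1, EXCLUDED)]
        table = amplification_table(result_from(assignments))
        assert list(table["root"]) == [10, 20]  # descending paralog count
        assert list(table["ratio"]) == [3.0, 4.0]
        assert (table["ratio"] >= 1.0).all()
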