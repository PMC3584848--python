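import pytest
from hypothesis import given, settings, strategies as st

from protofam import (
    AnnotationDB,
    StabilityParams,
    SyntheticSpec,
    annotation_summary,
    correspondence_score,
    gen_annotations,
    gen_similarity,
    infer_protein_annotations,
    map_proteome,
    protoname,
    protonames_for_tree,
    self_query_rows,
    specificity,
    build_tree,
    stable_clusters,
)
from protofam.cluster_tree import ClusterNode


def node(members, node_id=1):
    return ClusterNode(node_id=node_id, members=frozenset(members))


def db_from(records, universe):
    return AnnotationDB.from_records(records, universe)


class TestScores:
    def test_correspondence_examples(self):
        assert correspondence_score(frozenset("abc"), frozenset("abc")) == 1.0
        assert correspondence_score(frozenset("abcd"), frozenset("cde")) == 0.4
        assert correspondence_score(frozenset("ab"), frozenset("cd")) == 0.0

    def test_specificity_examples(self):
        assert specificity(frozenset("abc"), frozenset("abcz")) == 1.0
        assert specificity(frozenset("abcde"), frozenset("a")) == 0.2

    def test_empty_cluster_errors(self):
        for fn in (correspondence_score, specificity):
            with pytest.raises(ValueError):
                fn(frozenset(), frozenset("a"))

    @settings(max_examples=100, derandomize=True)
    @given(
        cluster=st.frozensets(st.integers(0, 30), min_size=1, max_size=15),
        term=st.frozensets(st.integers(0, 30), max_size=15),
    )
    def test_bounds_and_identity(self, cluster, term):
        cs = correspondence_score(cluster, term)
        spec = specificity(cluster, term)
        assert 0.0 <= cs <= 1.0
        assert 0.0 <= spec <= 1.0
        assert (cs == 1.0) == (cluster == term)
        # growing the term outside the cluster can only dilute CS
        grown = term | frozenset(range(100, 105))
        assert correspondence_score(cluster, grown) <= cs


class TestProtoName:
    UNIVERSE = [f"m{i}" for i in range(8)] + [f"x{i}" for i in range(40)]

    def test_small_clusters_are_never_named(self):
        db = db_from([(f"m{i}", "GO", "T1", "kinase") for i in range(4)], self.UNIVERSE)
        assert protoname(node([f"m{i}" for i in range(4)]), db) is None

    def test_blacklisted_terms_never_selected(self):
        members = [f"m{i}" for i in range(6)]
        records = [(pid, "Keyword", "T9", "Complete proteome") for pid in members]
        records += [(pid, "Keyword", "T2", "transporter") for pid in members[:3]]
        db = db_from(records, self.UNIVERSE)
        name = protoname(node(members), db)
        assert [t.term_id for t in name.terms] == ["T2"]

    def test_cs_tie_broken_by_intersection(self):
        members = [f"m{i}" for i in range(8)]
        # A: 6 carriers inside + 4 outside -> CS 6/12; B: 4 inside -> CS 4/8
        records = [(pid, "GO", "A", "term a") for pid in members[:6]]
        records += [(f"x{i}", "GO", "A", "term a") for i in range(4)]
        records += [(pid, "GO", "B", "term b") for pid in members[:4]]
        db = db_from(records, self.UNIVERSE)
        name = protoname(node(members), db)
        (term,) = name.terms
        assert term.cs == 0.5
        assert (term.term_id, term.n_intersect) == ("A", 6)

    def test_specificity_filter_applies_before_ranking(self):
        members = [f"m{i}" for i in range(8)]
        # X: CS 1/8 but specificity 1/8 < 0.2 -> filtered out
        # Y: CS 3/33 with specificity 3/8 >= 0.2 -> selected despite lower CS
        records = [("m0", "GO", "X", "rare exact term")]
        records += [(pid, "GO", "Y", "broad term") for pid in members[:3]]
        records += [(f"x{i}", "GO", "Y", "broad term") for i in range(30)]
        db = db_from(records, self.UNIVERSE)
        name = protoname(node(members), db)
        assert [t.term_id for t in name.terms] == ["Y"]

    def test_one_term_per_source(self):
        members = [f"m{i}" for i in range(6)]
        records = [(pid, "GO", "G1", "go term") for pid in members]
        records += [(pid, "Pfam", "P1", "pfam term") for pid in members]
        records += [(pid, "GO", "G2", "weaker go term") for pid in members[:2]]
        db = db_from(records, self.UNIVERSE)
        name = protoname(node(members), db)
        assert [(t.source, t.term_id) for t in name.terms] == [
            ("GO", "G1"), ("Pfam", "P1"),
        ]


class TestInference:
    def planted(self, purity=1.0, **kw):
        spec = SyntheticSpec(
            n_families=18,
            family_size_range=(5, 10),
            orphan_fraction=0.0,
            annotation_purity=purity,
            n_decoy_terms=0,
            **kw,
        )
        m, truth = gen_similarity(spec, 8)
        db = gen_annotations(truth, spec, 8)
        params = StabilityParams()
        tree = build_tree(m, params)
        stable = stable_clusters(tree, params)
        mapping = map_proteome(self_query_rows(m), tree, stable, params)
        return spec, truth, db, tree, mapping, params

    def test_terms_propagate_down_from_named_ancestors(self):
        # a protein mapped to a small unnamed sub-cluster inherits the
        # ProtoName of its family-granularity proroot
        from protofam.mapping import ProteinMapping
        from test_mapping import crafted_tree

        tree, fam_a, _ = crafted_tree()
        sub = fam_a - 2  # the 3-member chain prefix: below the naming size
        db = db_from(
            [(f"a{i}", "GO", "G1", "ion channel") for i in range(5)],
            tree.ids,
        )
        names = protonames_for_tree(tree, db)
        assert fam_a in names and sub not in names
        assignment = ProteinMapping("a0", sub, 0.1, fam_a)
        inferred = infer_protein_annotations(assignment, tree, names)
        assert inferred == {("GO", "G1", "ion channel")}

    def test_excluded_proteins_receive_nothing(self):
        _, truth, db, tree, mapping, params = self.planted()
        names = protonames_for_tree(tree, db)
        excluded = [a for a in mapping if a.is_excluded]
        assert excluded, "fixture should hold deep (PL > 70) families"
        for a in excluded:
            assert infer_protein_annotations(a, tree, names) == set()

    def test_blacklisted_terms_are_never_inferred(self):
        _, truth, db, tree, mapping, params = self.planted()
        blacklisted = {"complete proteome", "taxonomy", "hypothetical protein"}
        names = protonames_for_tree(tree, db)
        for a in mapping:
            for _, _, label in infer_protein_annotations(a, tree, names):
                assert label.lower() not in blacklisted

    def test_summary_fractions(self):
        _, truth, db, tree, mapping, params = self.planted(
            unannotated_family_fraction=0.25
        )
        names = protonames_for_tree(tree, db)
        inferences = {
            a.protein_id: infer_protein_annotations(a, tree, names) for a in mapping
        }
        summary = annotation_summary(mapping, names, inferences)
        # a quarter of the families were planted without any term
        assert summary["fraction_roots_named"] == pytest.approx(0.75, abs=0.15)
        assert 0.0 < summary["fraction_proteome_annotated"] <= 1.0
        assert set(summary["source_shares"]) <= {"GO", "InterPro", "Pfam", "Keyword"}

    def test_empty_db_gives_zero_coverage(self):
        _, truth, db, tree, mapping, params = self.planted(purity=0.0)
        names = protonames_for_tree(tree, db)
        assert names == {}
        inferences = {
            a.protein_id: infer_protein_annotations(a, tree, names) for a in mapping
        }
        summary = annotation_summary(mapping, names, inferences)
        assert summary["fraction_roots_named"] == 0.0
        assert summary["fraction_proteome_annotated"] == 0.0


class TestAnnotationDBIO:
    def test_load_drops_blacklisted_and_roundtrips(self, tmp_path):
        universe = ["a", "b", "c"]
        db = db_from(
            [
                ("a", "GO", "T1", "kinase"),
                ("b", "Keyword", "T2", "Complete Proteome"),
                ("c", "GO", "T3", "channel"),
            ],
            universe,
        )
        assert set(db.frame["term_id"]) == {"T1", "T3"}
        path = tmp_path / "ann.tsv"
        db.write(path)
        back = AnnotationDB.load(path, universe)
        assert back.frame.equals(db.frame)

    def test_duplicate_triples_deduplicated_at_load(self):
        db = db_from(
            [("a", "GO", "T1", "kinase"), ("a", "GO", "T1", "kinase")], ["a"]
        )
        assert len(db.frame) == 1

    def test_unknown_protein_rejected(self):
        import pandas as pd

        frame = pd.DataFrame(
            [("zz", "GO", "T1", "kinase")],
            columns=["protein_id", "source", "term_id", "term_label"],
        )
        with pytest.raises(ValueError, match="universe"):
            AnnotationDB(frame, frozenset({"a"}))
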