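"""Similarity search, target collection, expansion, and set partition."""
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugscout.chemistry import compute_fingerprint, parse_structure, tanimoto
from drugscout.errors import DrugscoutError, IntegrityError
from drugscout.knowledgebase import (
    TargetInteraction,
    load_compound_db,
    load_interaction_graph,
)
from drugscout.target_prediction import (
    TargetSet,
    collect_possible_targets,
    expand_by_neighbors,
    partition_sets,
    similarity_search,
)


def _db(tmp_path, entries):
    smi = tmp_path / "db.smi"
    smi.write_text("".join(f"{s}\t{i}\n" for i, s in entries))
    inter = tmp_path / "i.tsv"
    inter.write_text("compound_id\tprotein_id\n")
    records, _ = load_compound_db(smi, inter)
    return records


class TestSimilaritySearch:
    def test_exact_match_ranks_first(self, tmp_path):
        records = _db(tmp_path, [("a", "CCO"), ("b", "c1ccccc1CN")])
        q = {"q": compute_fingerprint(parse_structure("q", "CCO"))}
        hits = similarity_search(q, records, threshold=0.2)
        assert hits[0].db_compound_id == "a"
        assert hits[0].similarity == 1.0

    def test_threshold_one_without_exact_match(self, tmp_path):
        records = _db(tmp_path, [("a", "CCO")])
        q = {"q": compute_fingerprint(parse_structure("q", "CCCCN"))}
        assert similarity_search(q, records, threshold=1.0) == []

    def test_empty_database_rejected(self):
        with pytest.raises(DrugscoutError):
            similarity_search({}, [], threshold=0.7)

    def test_multi_query_keeps_max_similarity(self, tmp_path):
        records = _db(tmp_path, [("a", "CCO")])
        q = {
            "parent": compute_fingerprint(parse_structure("p", "CCO")),
            "metab": compute_fingerprint(parse_structure("m", "CCOC")),
        }
        hits = similarity_search(q, records, threshold=0.1)
        assert len(hits) == 1
        assert hits[0].similarity == 1.0
        assert hits[0].query_id == "parent"

    def test_matches_exhaustive_scan_on_fixture(self, study_dir):
        """Retained hits equal a brute-force Tanimoto scan of the whole db."""
        records, _ = load_compound_db(
            study_dir / "compounds.smi", study_dir / "interactions.tsv"
        )
        for q in parse_queries(study_dir):
            fp = compute_fingerprint(q)
            hits = similarity_search({q.id: fp}, records, threshold=0.7)
            expected = {
                r.compound_id for r in records if tanimoto(fp, r.fingerprint) >= 0.7
            }
            assert {h.db_compound_id for h in hits} == expected

    def test_threshold_monotonicity(self, study_dir):
        """Lowering the threshold never shrinks the hit set."""
        records, inters = load_compound_db(
            study_dir / "compounds.smi", study_dir / "interactions.tsv"
        )
        q = parse_queries(study_dir)[0]
        fp = {q.id: compute_fingerprint(q)}
        prev_hits: set[str] = set()
        prev_targets: set[str] = set()
        for thr in (0.9, 0.7, 0.5, 0.3):
            hits = similarity_search(fp, records, thr)
            targets = collect_possible_targets(hits, inters, q.id).members
            assert {h.db_compound_id for h in hits} >= prev_hits
            assert targets >= prev_targets
            prev_hits = {h.db_compound_id for h in hits}
            prev_targets = targets
        assert prev_targets


def parse_queries(study_dir):
    from drugscout.chemistry import read_smiles_file

    return read_smiles_file(study_dir / "queries.smi")


class TestCollectTargets:
    def test_empty_hits_empty_set(self):
        t = collect_possible_targets([], [], "d")
        assert t.members == set()
        assert t.stage == "possible"

    def test_union_with_provenance(self, tmp_path):
        records = _db(tmp_path, [("a", "CCO"), ("b", "CCO")])
        q = {"q": compute_fingerprint(parse_structure("q", "CCO"))}
        hits = similarity_search(q, records, threshold=0.9)
        inters = [
            TargetInteraction("a", "P1"),
            TargetInteraction("b", "P1"),
            TargetInteraction("b", "P2"),
        ]
        t = collect_possible_targets(hits, inters, "drug")
        assert t.members == {"P1", "P2"}
        assert len(t.provenance["P1"]) == 2

    def test_equals_relational_join(self, study_dir):
        """Collected set equals the brute-force join of hits x interactions."""
        records, inters = load_compound_db(
            study_dir / "compounds.smi", study_dir / "interactions.tsv"
        )
        q = parse_queries(study_dir)[0]
        hits = similarity_search(
            {q.id: compute_fingerprint(q)}, records, threshold=0.7
        )
        t = collect_possible_targets(hits, inters, q.id)
        hit_ids = {h.db_compound_id for h in hits}
        expected = {i.protein_id for i in inters if i.compound_id in hit_ids}
        assert t.members == expected


class TestExpansion:
    def test_star_graph(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        t = TargetSet(drug_id="d", stage="possible", members={0})
        assert expand_by_neighbors(t, g).members == {0, 1, 2, 3, 4}

    def test_isolated_seed_unchanged(self):
        g = nx.Graph()
        t = TargetSet(drug_id="d", stage="possible", members={"lonely"})
        out = expand_by_neighbors(t, g)
        assert out.members == {"lonely"}
        assert out.stage == "expanded"

    def test_expanded_superset_on_fixture(self, study_dir):
        records, inters = load_compound_db(
            study_dir / "compounds.smi", study_dir / "interactions.tsv"
        )
        g = load_interaction_graph(study_dir / "ppi_edges.tsv")
        for q in parse_queries(study_dir):
            hits = similarity_search(
                {q.id: compute_fingerprint(q)}, records, threshold=0.7
            )
            possible = collect_possible_targets(hits, inters, q.id)
            expanded = expand_by_neighbors(possible, g)
            assert expanded.members >= possible.members
            # one hop: every added protein is adjacent to a seed
            for added in expanded.members - possible.members:
                assert any(g.has_edge(added, s) for s in possible.members)

    def test_requires_possible_stage(self):
        t = TargetSet(drug_id="d", stage="expanded", members=set())
        with pytest.raises(ValueError):
            expand_by_neighbors(t, nx.Graph())


def classify_by_membership(sets):
    """Independent element-wise oracle for the partition semantics."""
    drugs = sorted(sets)
    out = {"common": set(), "similar": {}, "unique": {d: set() for d in drugs}, "multi": {}}
    for el in set().union(*sets.values()):
        holders = tuple(d for d in drugs if el in sets[d])
        if len(holders) == len(drugs):
            out["common"].add(el)
        elif len(holders) == 1:
            out["unique"][holders[0]].add(el)
        elif len(holders) == 2:
            out["similar"].setdefault(holders, set()).add(el)
        else:
            out["multi"].setdefault(holders, set()).add(el)
    return out


class TestPartition:
    def test_worked_three_set_example(self):
        part = partition_sets({"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6}})
        assert part.common == {4}
        assert part.similar[("A", "B")] == {3}
        assert part.similar[("B", "C")] == {5}
        assert part.similar[("A", "C")] == set()
        assert part.unique == {"A": {1, 2}, "B": set(), "C": {6}}

    def test_identical_sets_all_common(self):
        part = partition_sets({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert part.common == {1, 2}
        assert all(not v for v in part.similar.values())
        assert all(not v for v in part.unique.values())

    def test_disjoint_sets_all_unique(self):
        part = partition_sets({"A": {1}, "B": {2}, "C": {3}})
        assert part.common == set()
        assert part.unique == {"A": {1}, "B": {2}, "C": {3}}

    def test_duplicate_drug_rejected(self):
        with pytest.raises(IntegrityError):
            partition_sets([("A", {1}), ("A", {2})])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            partition_sets({"A": {1}})

    def test_k4_multi_class(self):
        sets = {d: {1} for d in "ABC"}
        sets["D"] = {2}
        part = partition_sets(sets)
        assert part.multi == {("A", "B", "C"): {1}}
        assert part.unique["D"] == {2}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.fixed_dictionaries(
            {d: st.sets(st.integers(0, 30), max_size=15) for d in "XYZ"}
        )
    )
    def test_matches_membership_oracle(self, sets):
        """Partition equals independent per-element classification; the
        classes are disjoint and cover the union."""
        if any(not s for s in sets.values()):
            sets = {d: s | {99} for d, s in sets.items()}  # keep sets nonempty
        part = partition_sets(sets)
        oracle = classify_by_membership(sets)
        assert part.common == oracle["common"]
        assert {k: v for k, v in part.similar.items() if v} == oracle["similar"]
        assert part.unique == oracle["unique"]
        # disjoint and covering
        classes = [part.common, *part.similar.values(), *part.unique.values(),
                   *part.multi.values()]
        total = sum(len(c) for c in classes)
        union = set().union(*classes) if classes else set()
        assert total == len(union) == len(set().union(*sets.values()))
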