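"""Clonal clustering semantics and drop-in query tracing."""

import numpy as np
import pytest

import iglineage as ig
from iglineage import Repertoire
from iglineage.airr_io import RecordValidationError
from iglineage.clonotype import cluster_clones, merge_compartments, trace_query
from iglineage.distance import normalized_hamming

from conftest import founder_query, make_record


class TestMergeCompartments:
    def test_concatenation_preserves_labels(self):
        n = Repertoire(records=[make_record(f"n{i}") for i in range(3)], subject="P1", compartment="N")
        m = Repertoire(records=[make_record(f"m{i}") for i in range(2)], subject="P1", compartment="M")
        out = merge_compartments([n, m])
        assert len(out) == 5
        assert [r.compartment for r in out] == ["N"] * 3 + ["M"] * 2
        assert out.compartment == "merged"

    def test_single_repertoire_identity(self):
        n = Repertoire(records=[make_record("a")], subject="P1", compartment="N")
        out = merge_compartments([n])
        assert [r.sequence_id for r in out] == ["a"]

    def test_colliding_ids_get_compartment_prefix(self):
        n = Repertoire(records=[make_record("s1", compartment="N")], subject="P1", compartment="N")
        m = Repertoire(records=[make_record("s1", compartment="M")], subject="P1", compartment="M")
        out = merge_compartments([n, m])
        assert [r.sequence_id for r in out] == ["N|s1", "M|s1"]

    def test_mixed_subjects_rejected(self):
        a = Repertoire(records=[], subject="P1")
        b = Repertoire(records=[], subject="P2")
        with pytest.raises(ValueError, match="subjects"):
            merge_compartments([a, b])


def _chain_fixture():
    # junction length 10; pairwise mismatches A-B=1, B-C=2, A-C=3; D far away
    junctions = {
        "A": "AAAAAAAAAA",
        "B": "AAAAAAAAAT",
        "C": "AAAAAAATTT",
        "D": "GGGGGGGGGG",
    }
    return Repertoire(
        records=[make_record(sid, junction=j) for sid, j in junctions.items()],
        subject="P1",
    )


class TestClusterClones:
    def test_single_linkage_chains(self):
        out = cluster_clones(_chain_fixture(), threshold=0.2)
        groups = {frozenset(ids) for ids in out.clones.values()}
        assert groups == {frozenset({"A", "B", "C"}), frozenset({"D"})}

    def test_complete_linkage_splits_the_chain(self):
        out = cluster_clones(_chain_fixture(), threshold=0.2, linkage="complete")
        by_clone = {frozenset(ids) for ids in out.clones.values()}
        # A-C distance 0.3 > 0.2 so the chain cannot be one complete-linkage clone
        assert frozenset({"A", "B", "C"}) not in by_clone

    def test_different_junction_lengths_never_co_cluster(self):
        rep = Repertoire(
            records=[
                make_record("a", junction="AAAAAAAAAA"),
                make_record("b", junction="AAAAAAAAAAA"),
            ]
        )
        out = cluster_clones(rep, threshold=1.0)
        assert out.assignment["a"] != out.assignment["b"]

    def test_intersecting_gene_sets_are_compatible(self):
        rep = Repertoire(
            records=[
                make_record("a", v="IGHV1-2*01"),
                make_record("b", v="IGHV1-2*01,IGHV1-3*01"),
            ]
        )
        out = cluster_clones(rep, threshold=0.0)
        assert out.assignment["a"] == out.assignment["b"]

    def test_transitive_set_compatibility_bridges_partitions(self):
        # a∩b and b∩c intersect but a∩c do not: all in one partition ("act set")
        rep = Repertoire(
            records=[
                make_record("a", v="IGHV1-1*01"),
                make_record("b", v="IGHV1-1*01,IGHV2-1*01"),
                make_record("c", v="IGHV2-1*01"),
            ]
        )
        out = cluster_clones(rep, threshold=0.0)
        assert len(set(out.assignment.values())) == 1

    def test_empty_input(self):
        out = cluster_clones(Repertoire(), threshold=0.1)
        assert out.assignment == {} and out.clones == {}

    def test_determinism_and_id_format(self):
        a = cluster_clones(_chain_fixture(), threshold=0.2)
        b = cluster_clones(_chain_fixture(), threshold=0.2)
        assert a.assignment == b.assignment
        assert all(cid.startswith("P1_") for cid in a.clones)


def _random_repertoire(rng, n):
    junctions = ["".join(rng.choice(list("ACGT"), size=rng.choice([9, 12]))) for _ in range(n)]
    vs = ["IGHV1-1*01", "IGHV2-1*01", "IGHV1-1*01,IGHV2-1*01"]
    return Repertoire(
        records=[
            make_record(f"r{i}", junction=j, v=str(rng.choice(vs))) for i, j in enumerate(junctions)
        ],
        subject="S",
    )


def _brute_force_clones(rep, threshold):
    """O(n^2) transitive closure over the pairwise clonal relation."""
    recs = rep.records
    n = len(recs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    related = lambda a, b: (
        len(a.junction) == len(b.junction)
        and a.v_genes & b.v_genes
        and a.j_genes & b.j_genes
        and normalized_hamming(a.junction, b.junction) <= threshold
    )
    for i in range(n):
        for j in range(i + 1, n):
            if related(recs[i], recs[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(recs[i].sequence_id)
    return {frozenset(g) for g in groups.values()}


@pytest.mark.parametrize("threshold", [0.05, 0.1, 0.2])
def test_clustering_matches_brute_force_oracle(threshold):
    rng = np.random.default_rng(hash(threshold) % 2**31)
    for _ in range(30):
        rep = _random_repertoire(rng, int(rng.integers(2, 16)))
        out = cluster_clones(rep, threshold)
        got = {frozenset(ids) for ids in out.clones.values()}
        assert got == _brute_force_clones(rep, threshold)


def test_raising_threshold_never_splits_clones():
    rng = np.random.default_rng(7)
    for _ in range(15):
        rep = _random_repertoire(rng, 12)
        lo = cluster_clones(rep, 0.1)
        hi = cluster_clones(rep, 0.3)
        coarse = {sid: hi.assignment[sid] for sid in lo.assignment}
        for ids in lo.clones.values():
            assert len({coarse[sid] for sid in ids}) == 1


class TestTraceQuery:
    def test_isolated_query_forms_singleton_group(self):
        rep = Repertoire(records=[make_record("far", junction="GGGGGGGG")], subject="S")
        q = make_record("q", junction="AAAAAAAAAA")
        group = trace_query(q, rep, threshold=0.2)
        assert group.member_ids() == ["q"]
        assert group.query_id == "q"

    def test_query_missing_annotations_rejected(self):
        q = make_record("q")
        object.__setattr__(q, "junction", "")
        with pytest.raises(RecordValidationError):
            trace_query(q, Repertoire(), threshold=0.1)

    def test_colliding_query_id_is_renamed(self):
        rep = Repertoire(records=[make_record("q")], subject="S")
        group = trace_query(make_record("q"), rep, threshold=0.1)
        assert group.query_id == "query|q"
        assert set(group.member_ids()) == {"q", "query|q"}

    def test_prefilter_equals_full_repertoire_clustering(self):
        rng = np.random.default_rng(3)
        for trial in range(15):
            rep = _random_repertoire(rng, 12)
            q = make_record("qq", junction=rep.records[0].junction[:-1] + "T",
                            v=",".join(sorted(rep.records[0].v_call)))
            group = trace_query(q, rep, threshold=0.15)
            full = Repertoire(records=[q] + rep.records, subject="S")
            assignment = cluster_clones(full, 0.15)
            expected = set(assignment.clones[assignment.assignment["qq"]])
            assert set(group.member_ids()) == expected

    def test_simulated_clones_recovered_exactly(self, sim_subject):
        """Tracing one member per planted clone returns exactly the clone's
        surviving repertoire records."""
        from iglineage.distance import dist_to_nearest, find_threshold
        from iglineage.preprocess import trim_to_cdr1_fwr4

        truth, merged = sim_subject["truth"], sim_subject["merged"]
        t = find_threshold(dist_to_nearest(merged))
        clone_of = dict(zip(truth.records.sequence_id, truth.records.clone_id))
        survivors = {r.sequence_id for r in merged.records}
        clones_ix = sim_subject["truth"].clones.set_index("clone_id")
        real = truth.records[~truth.records.clone_id.str.startswith("junk")]
        for clone_id in real.clone_id.unique()[:10]:
            q = trim_to_cdr1_fwr4(founder_query(truth, clones_ix, clone_id))
            group = trace_query(q, merged, t)
            got = {m.sequence_id for m in group.non_query_members()}
            expected = {sid for sid in survivors if clone_of[sid] == clone_id}
            assert got == expected
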