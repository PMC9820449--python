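"""Fitch parsimony, topology search and lineage-graph construction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from iglineage.clonotype import ClonotypeGroup
from iglineage.distance import hamming_mismatches
from iglineage.germline import UcaSequence
from iglineage.phylogeny import (
    build_lineage_tree,
    enumerate_topologies,
    export_tree,
    fitch_score,
    import_graphml,
    search_mp,
    to_lineage_graph,
)

from conftest import make_record


def _rand_seqs(rng, n, length):
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(list("ACGT"), size=length)))
    return sorted(seqs)


class TestFitch:
    def test_single_leaf_scores_zero(self):
        g = nx.Graph()
        g.add_node(0)
        assert fitch_score(g, ["ACGT"]) == 0

    def test_two_leaves_score_equals_hamming(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        assert fitch_score(g, ["ACGT", "ACGA"]) == 1
        assert fitch_score(g, ["ACGT", "TGCA"]) == 4

    def test_quartet_minimum_is_three(self):
        # {"AA","AT","TA","TT"}: every one of the 3 unrooted quartet
        # topologies needs >= 3 substitutions and the best achieves exactly 3
        seqs = ["AA", "AT", "TA", "TT"]
        topologies = list(enumerate_topologies(4))
        assert len(topologies) == 3
        scores = [fitch_score(t, seqs) for t in topologies]
        assert min(scores) == 3

    def test_ambiguous_symbols_are_free(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        assert fitch_score(g, ["NNGT", "ACGT"]) == 0

    def test_unequal_lengths_raise(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        with pytest.raises(ValueError, match="length"):
            fitch_score(g, ["ACG", "ACGT"])

    def test_score_lower_bounds(self):
        # per-site distinct states minus one, the variable-site count and the
        # max pairwise Hamming distance all bound the score from below; the
        # per-site union count bounds it from above
        rng = np.random.default_rng(5)
        seqs = _rand_seqs(rng, 5, 8)
        states = sum(len({s[i] for s in seqs}) - 1 for i in range(8))
        variable = sum(1 for i in range(8) if len({s[i] for s in seqs}) > 1)
        max_pair = max(
            sum(x != y for x, y in zip(a, b)) for a in seqs for b in seqs
        )
        upper = variable * (len(seqs) - 1)
        for topo in itertools.islice(enumerate_topologies(5), 5):
            score = fitch_score(topo, seqs)
            assert max(states, variable, max_pair) <= score <= upper


def test_topology_counts_follow_double_factorial():
    assert len(list(enumerate_topologies(4))) == 3
    assert len(list(enumerate_topologies(5))) == 15
    assert len(list(enumerate_topologies(6))) == 105


class TestSearch:
    def test_two_sequences(self):
        res = search_mp(["ACGT", "AGGA"])
        assert res.score == 2 and res.exact

    def test_heuristic_matches_exhaustive_on_small_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            seqs = _rand_seqs(rng, n, int(rng.integers(6, 13)))
            exact = search_mp(seqs, max_exhaustive=7).score
            heuristic = search_mp(seqs, max_exhaustive=3, seed=int(rng.integers(100))).score
            assert heuristic >= exact  # heuristic can't beat the optimum
            exhaustive_min = min(fitch_score(t, seqs) for t in enumerate_topologies(n))
            assert exact == exhaustive_min

    def test_exhaustive_score_is_input_order_invariant(self):
        rng = np.random.default_rng(1)
        seqs = _rand_seqs(rng, 5, 10)
        assert search_mp(seqs).score == search_mp(seqs[::-1]).score

    def test_cooptimal_count_reported_when_exhaustive(self):
        res = search_mp(["AA", "AT", "TA", "TT"])
        assert res.exact and res.n_cooptimal >= 1

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            search_mp(["ACGT"])

    def test_duplicate_sequences_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            search_mp(["ACGT", "ACGT"])


def _group_for(seq_counts, uca_seq, mask=(0, 0)):
    members = []
    for i, (seq, count) in enumerate(seq_counts):
        members.append(
            make_record(
                f"m{i}", sequence=seq, junction=seq[:4], duplicate_count=count,
                compartment="N", isotype="IgM",
            )
        )
    group = ClonotypeGroup("c1", members=members)
    group.uca = UcaSequence(
        sequence=uca_seq, v_gene="IGHV1-1", j_gene="IGHJ1-1",
        mask_start=mask[0], mask_end=mask[1],
    )
    return group


class TestLineageGraph:
    def test_two_node_chain(self):
        group = _group_for([("ACGTACGA", 5)], "ACGTACGT")
        tree = build_lineage_tree(group)
        assert tree.root == "UCA"
        assert tree.graph.number_of_nodes() == 2
        (child,) = tree.graph.successors("UCA")
        assert tree.graph.edges["UCA", child]["weight"] == 1
        assert tree.graph.nodes[child]["copy_count"] == 5

    def test_simulated_chain_path_lengths_sum_to_score(self):
        # UCA -> X (1 mutation) -> Y (2 more): total parsimony cost 3
        uca = "ACGTACGTACGT"
        x = "ACGTACGTACGA"
        y = "ACGTACGAACCA"
        tree = build_lineage_tree(_group_for([(x, 2), (y, 3)], uca))
        assert tree.edge_weight_sum() == 3
        assert tree.edge_weight_sum() == tree.labeling_score()

    def test_zero_shm_member_merges_into_root(self):
        uca = "ACGTACGTACGT"
        tree = build_lineage_tree(_group_for([(uca, 9), ("ACGTACGTACGA", 1)], uca))
        assert tree.graph.nodes["UCA"]["copy_count"] == 9
        assert all(d["weight"] >= 1 for _, _, d in tree.graph.edges(data=True))

    def test_masked_root_positions_cost_nothing(self):
        uca = "NNNNACGTACGT"
        member = "TTTTACGTACGT"
        tree = build_lineage_tree(_group_for([(member, 4)], uca, mask=(0, 4)))
        assert tree.graph.number_of_nodes() == 1  # member is the root under the mask
        assert tree.graph.nodes["UCA"]["copy_count"] == 4

    def test_uca_must_be_among_sequences(self):
        group = _group_for([("ACGTACGA", 5)], "ACGTACGT")
        topo = nx.Graph()
        topo.add_edge(0, 1)
        with pytest.raises(ValueError, match="UCA"):
            to_lineage_graph(topo, ["ACGTACGA", "TTTTTTTT"], group.uca, group)

    def test_tree_contract_on_simulated_lineages(self, sim_subject):
        """Single germline root, weights >= 1, edge sum == labeling score,
        root-to-leaf path sums >= direct Hamming distances."""
        from iglineage.clonotype import trace_query
        from iglineage.distance import dist_to_nearest, find_threshold
        from iglineage.germline import attach_uca, build_uca
        from iglineage.preprocess import trim_to_cdr1_fwr4

        from conftest import founder_query

        truth, merged, ref = sim_subject["truth"], sim_subject["merged"], sim_subject["ref"]
        clones_ix = truth.clones.set_index("clone_id")
        t = find_threshold(dist_to_nearest(merged))
        checked = 0
        for clone_id in clones_ix.index:
            if checked >= 8:
                break
            q = trim_to_cdr1_fwr4(founder_query(truth, clones_ix, clone_id))
            group = trace_query(q, merged, t)
            if len(group.members) < 2:
                continue
            attach_uca(group, build_uca(group, ref))
            tree = build_lineage_tree(group, seed=3)
            g = tree.graph
            assert nx.is_arborescence(g) or g.number_of_nodes() == 1
            roots = [n for n, d in g.nodes(data=True) if d["is_germline"]]
            assert roots == [tree.root]
            assert all(d["weight"] >= 1 for _, _, d in g.edges(data=True))
            assert tree.edge_weight_sum() == tree.labeling_score()
            root_seq = g.nodes[tree.root]["sequence"]
            for leaf in (n for n in g.nodes if g.out_degree(n) == 0):
                path = nx.shortest_path(g, tree.root, leaf)
                path_w = sum(
                    g.edges[a, b]["weight"] for a, b in zip(path, path[1:])
                )
                assert path_w >= hamming_mismatches(root_seq, g.nodes[leaf]["sequence"])
            checked += 1
        assert checked >= 5


class TestExport:
    def _tree(self):
        uca = "ACGTACGTACGT"
        return build_lineage_tree(
            _group_for([("ACGTACGTACGA", 2), ("ACGTACGAACCA", 3)], uca)
        )

    def test_newick_shape_and_dendropy_parse(self, tmp_path):
        import dendropy

        tree = self._tree()
        p = tmp_path / "t.nwk"
        export_tree(tree, p, "newick")
        text = p.read_text()
        assert text.strip().endswith("UCA;") or "UCA" in text
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        total = sum(e.length for e in parsed.edges() if e.length is not None)
        assert total == tree.edge_weight_sum()

    def test_two_node_newick(self, tmp_path):
        tree = build_lineage_tree(_group_for([("ACGTACGA", 5)], "ACGTACGT"))
        p = tmp_path / "two.nwk"
        export_tree(tree, p, "newick")
        text = p.read_text().strip()
        assert text.startswith("(") and ":1" in text
        assert text.split(")")[-1].startswith("UCA") and text.endswith(";")

    def test_graphml_round_trip(self, tmp_path):
        tree = self._tree()
        p = tmp_path / "t.graphml"
        export_tree(tree, p, "graphml")
        back = import_graphml(p)
        assert back.root == tree.root
        assert set(back.graph.nodes) == set(tree.graph.nodes)
        for n in tree.graph.nodes:
            for key in ("sequence", "copy_count", "compartments", "isotypes", "is_inferred"):
                assert back.graph.nodes[n][key] == tree.graph.nodes[n][key]
        assert set(back.graph.edges) == set(tree.graph.edges)
        assert back.edge_weight_sum() == tree.edge_weight_sum()

    def test_dot_has_one_statement_per_node_and_edge(self, tmp_path):
        tree = self._tree()
        p = tmp_path / "t.dot"
        export_tree(tree, p, "dot")
        lines = p.read_text().splitlines()
        node_lines = [l for l in lines if "copy_count=" in l]
        edge_lines = [l for l in lines if "->" in l]
        assert len(node_lines) == tree.graph.number_of_nodes()
        assert len(edge_lines) == tree.graph.number_of_edges()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_tree(self._tree(), tmp_path / "x", "svg")
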