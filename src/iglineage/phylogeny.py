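"""Germline-rooted maximum-parsimony lineage trees.

Tree search runs on unrooted binary topologies over the distinct sequences of
a clonotype group (UCA included as an ordinary leaf): exhaustive enumeration
up to ``max_exhaustive`` leaves, seeded stepwise addition plus
nearest-neighbor-interchange hill climbing beyond.  The scored topology is
then converted to a clonal lineage graph: internal sequences are assigned by
a minimum-score Fitch backtrace (ambiguities resolved toward the parent
state), the tree is rooted at the UCA, zero-weight edges are contracted, and
node metadata (copy counts, compartments, isotypes) is aggregated from the
group members.  Ambiguous symbols (the UCA's D-mask ``N`` run) behave as full
nucleotide sets and therefore never cost a substitution.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import networkx as nx
import numpy as np

from .airr_io import IgHRecord
from .clonotype import ClonotypeGroup
from .distance import hamming_mismatches
from .germline import UcaSequence

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BIT_TO_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}
_FULL = 15


def _encode(seq: str) -> np.ndarray:
    return np.array([_BITS.get(c, _FULL) for c in seq], dtype=np.uint8)


class MPResult(NamedTuple):
    """A searched topology with its parsimony score."""

    topology: nx.Graph
    score: int
    n_cooptimal: int | None  # co-optimal tree count when search was exhaustive
    exact: bool


def _leaf_star(leaves: list[int]) -> nx.Graph:
    g = nx.Graph()
    if len(leaves) == 1:
        g.add_node(leaves[0])
    elif len(leaves) == 2:
        g.add_edge(leaves[0], leaves[1])
    else:
        hub = -1
        for leaf in leaves:
            g.add_edge(hub, leaf)
    return g


def _insert_leaf(tree: nx.Graph, edge: tuple, leaf: int, new_internal: int) -> nx.Graph:
    out = tree.copy()
    u, v = edge
    out.remove_edge(u, v)
    out.add_edge(u, new_internal)
    out.add_edge(new_internal, v)
    out.add_edge(new_internal, leaf)
    return out


def enumerate_topologies(n: int) -> Iterator[nx.Graph]:
    """All unrooted binary topologies over leaves 0..n-1 ((2n-5)!! of them).

    Internal nodes are negative integers.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    base = _leaf_star(list(range(min(n, 3))))
    if n <= 3:
        yield base
        return

    def grow(tree: nx.Graph, next_leaf: int, next_internal: int) -> Iterator[nx.Graph]:
        if next_leaf == n:
            yield tree
            return
        for edge in list(tree.edges()):
            yield from grow(
                _insert_leaf(tree, edge, next_leaf, next_internal), next_leaf + 1, next_internal - 1
            )

    yield from grow(base, 3, -2)


def fitch_score(topology: nx.Graph, seqs: list[str]) -> int:
    """Minimum substitution count of the topology (Fitch small parsimony).

    Leaves are the integer nodes >= 0 indexing ``seqs``; sequences must share
    one length.  Ambiguous symbols count as the full nucleotide set.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    leaves = [v for v in topology.nodes if v >= 0]
    if len(leaves) == 1:
        return 0
    sets, score = _fitch_up(topology, seqs, root=leaves[0])
    return score


def _fitch_up(
    topology: nx.Graph, seqs: list[str], root: int
) -> tuple[dict[int, np.ndarray], int]:
    """Bottom-up Fitch pass rooted at a leaf; returns per-node sets and score."""
    encoded = {v: _encode(seqs[v]) for v in topology.nodes if v >= 0}
    sets: dict[int, np.ndarray] = {}
    score = 0
    order = list(nx.dfs_postorder_nodes(topology, source=root))
    parent = dict(nx.dfs_predecessors(topology, source=root))
    for node in order:
        children = [c for c in topology.neighbors(node) if parent.get(c) == node]
        if node >= 0 and node != root:
            sets[node] = encoded[node]
            continue
        acc = encoded[node] if node >= 0 else None
        for c in children:
            cs = sets[c]
            if acc is None:
                acc = cs
                continue
            inter = acc & cs
            empty = inter == 0
            score += int(empty.sum())
            acc = np.where(empty, acc | cs, inter)
        sets[node] = acc
    return sets, score


def search_mp(seqs: list[str], max_exhaustive: int = 7, seed: int = 0) -> MPResult:
    """Find a maximum-parsimony topology for distinct equal-length sequences.

    Exact (exhaustive enumeration) for n <= ``max_exhaustive``; otherwise
    seeded stepwise addition followed by NNI hill climbing to a local
    optimum.  Deterministic given (seqs, seed).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(seqs)) != n:
        raise ValueError("sequences must be distinct")
    if n <= max_exhaustive:
        best_tree, best_score, n_best = None, None, 0
        for topo in enumerate_topologies(n):
            s = fitch_score(topo, seqs)
            if best_score is None or s < best_score:
                best_tree, best_score, n_best = topo, s, 1
            elif s == best_score:
                n_best += 1
        return MPResult(best_tree, best_score, n_best, True)

    rng = np.random.default_rng(seed)
    order = [int(i) for i in rng.permutation(n)]
    tree = _leaf_star(order[:3])
    next_internal = -2
    for leaf in order[3:]:
        best_tree, best_score = None, None
        for edge in sorted(tree.edges()):
            cand = _insert_leaf(tree, edge, leaf, next_internal)
            s = fitch_score(cand, seqs)
            if best_score is None or s < best_score:
                best_tree, best_score = cand, s
        tree, next_internal = best_tree, next_internal - 1
    score = fitch_score(tree, seqs)
    improved = True
    while improved:
        improved = False
        for tree2, score2 in _nni_neighbors(tree, seqs):
            if score2 < score:
                tree, score = tree2, score2
                improved = True
                break
    return MPResult(tree, score, None, False)


def _nni_neighbors(tree: nx.Graph, seqs: list[str]) -> Iterator[tuple[nx.Graph, int]]:
    for u, v in sorted(tree.edges()):
        if u >= 0 or v >= 0:
            continue
        u_rest = sorted(set(tree.neighbors(u)) - {v})
        v_rest = sorted(set(tree.neighbors(v)) - {u})
        if len(u_rest) < 2 or len(v_rest) < 1:
            continue
        b = u_rest[1]
        for x in v_rest:
            swapped = tree.copy()
            swapped.remove_edge(u, b)
            swapped.remove_edge(v, x)
            swapped.add_edge(u, x)
            swapped.add_edge(v, b)
            yield swapped, fitch_score(swapped, seqs)


@dataclass
class LineageTree:
    """Germline-rooted clonal lineage graph.

    ``graph`` is a directed tree; every node carries sequence, copy_count,
    compartments/isotypes (Counters), is_germline and is_inferred; every edge
    carries ``weight`` = Hamming distance between its node sequences.
    """

    graph: nx.DiGraph
    root: str

    def edge_weight_sum(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def labeling_score(self) -> int:
        """Substitution count of the realized labeling (wildcard-tolerant)."""
        return sum(
            hamming_mismatches(self.graph.nodes[u]["sequence"], self.graph.nodes[v]["sequence"])
            for u, v in self.graph.edges()
        )


def _assign_internal(topology: nx.Graph, seqs: list[str], root: int) -> dict[int, str]:
    """Minimum-score labeling by Fitch backtrace, preferring the parent state."""
    if topology.number_of_nodes() == 1:
        return {root: seqs[root]}
    sets, _ = _fitch_up(topology, seqs, root=root)
    parent = dict(nx.dfs_predecessors(topology, source=root))
    labels: dict[int, str] = {v: seqs[v] for v in topology.nodes if v >= 0}
    root_seq = _encode(seqs[root])
    states: dict[int, np.ndarray] = {root: root_seq}
    for node in nx.dfs_preorder_nodes(topology, source=root):
        if node == root:
            continue
        p_state = states[parent[node]]
        if node >= 0:
            states[node] = _encode(seqs[node])
            continue
        own = sets[node]
        keep = (own & p_state) != 0
        chosen = np.where(keep, own & p_state, own)
        # collapse multi-bit states to their smallest base deterministically
        low = chosen & (-chosen.astype(np.int16)).astype(np.uint8)
        states[node] = low.astype(np.uint8)
        labels[node] = "".join(_BIT_TO_BASE[int(b)] for b in states[node])
    # realize the root's ambiguous positions (the UCA's D-mask) from its
    # child's state: cost-free, and makes every node sequence concrete so
    # zero-weight edges imply sequence equality and contraction is exact
    child = next(iter(topology.neighbors(root)))
    child_seq = labels[child]
    labels[root] = "".join(
        child_seq[i] if seqs[root][i] not in _BITS else seqs[root][i]
        for i in range(len(child_seq))
    )
    return labels


def to_lineage_graph(
    topology: nx.Graph,
    seqs: list[str],
    uca: UcaSequence,
    group: ClonotypeGroup,
) -> LineageTree:
    """Convert a scored topology into the rooted clonal lineage graph.

    Roots at the UCA, realizes internal sequences, contracts zero-weight
    edges (merging inferred nodes into identical observed nodes) and
    aggregates member metadata per distinct sequence.
    """
    try:
        uca_idx = seqs.index(uca.sequence)
    except ValueError:
        raise ValueError("the UCA sequence is not among the tree's input sequences")
    labels = _assign_internal(topology, seqs, root=uca_idx)

    members_by_seq: dict[str, list[IgHRecord]] = {}
    for m in group.members:
        if m.is_germline:
            continue
        members_by_seq.setdefault(m.sequence, []).append(m)

    g = nx.DiGraph()
    name: dict[int, str] = {}
    n_inferred = 0
    for node in topology.nodes:
        seq = labels[node]
        if node >= 0:
            nid = f"seq{node}" if node != uca_idx else "UCA"
        else:
            n_inferred += 1
            nid = f"inferred{n_inferred}"
        name[node] = nid
        if node == uca_idx:
            # members whose read equals the (unrealized) UCA sequence have no
            # leaf of their own; their metadata belongs on the root
            members = members_by_seq.get(uca.sequence, [])
        elif node >= 0:
            members = members_by_seq.get(seq, [])
        else:
            members = []
        g.add_node(
            nid,
            sequence=seq,
            copy_count=sum(m.duplicate_count for m in members),
            compartments=Counter(m.compartment for m in members),
            isotypes=Counter(m.isotype for m in members),
            is_germline=(node == uca_idx),
            is_inferred=(node < 0),
        )
    if topology.number_of_nodes() > 1:
        for u, v in nx.bfs_tree(topology, uca_idx).edges():
            w = hamming_mismatches(labels[u], labels[v])
            g.add_edge(name[u], name[v], weight=w)

    root = "UCA"
    g = _contract_zero_edges(g, root)
    return LineageTree(graph=g, root=root)


def _contract_zero_edges(g: nx.DiGraph, root: str) -> nx.DiGraph:
    def priority(nid: str) -> int:
        d = g.nodes[nid]
        if d["is_germline"]:
            return 0
        if not d["is_inferred"]:
            return 1
        return 2

    changed = True
    while changed:
        changed = False
        for u, v, d in sorted(g.edges(data=True)):
            if d["weight"] != 0:
                continue
            keep, drop = (u, v) if priority(u) <= priority(v) else (v, u)
            kd, dd = g.nodes[keep], g.nodes[drop]
            kd["copy_count"] += dd["copy_count"]
            kd["compartments"] = kd["compartments"] + dd["compartments"]
            kd["isotypes"] = kd["isotypes"] + dd["isotypes"]
            for p in list(g.predecessors(drop)):
                if p != keep:
                    g.add_edge(
                        p, keep,
                        weight=hamming_mismatches(g.nodes[p]["sequence"], kd["sequence"]),
                    )
            for c in list(g.successors(drop)):
                if c != keep:
                    g.add_edge(
                        keep, c,
                        weight=hamming_mismatches(kd["sequence"], g.nodes[c]["sequence"]),
                    )
            g.remove_node(drop)
            changed = True
            break
    # re-orient away from the root (contraction can only merge, but be safe)
    tree = nx.bfs_tree(g.to_undirected(), root)
    for u, v in tree.edges():
        if not g.has_edge(u, v):
            w = g.edges[v, u]["weight"]
            g.remove_edge(v, u)
            g.add_edge(u, v, weight=w)
    return g


def build_lineage_tree(group: ClonotypeGroup, seed: int = 0, max_exhaustive: int = 7) -> LineageTree:
    """Search a parsimony topology for a clonotype group and root it at its UCA."""
    if group.uca is None:
        raise ValueError("attach a UCA to the group before building its lineage tree")
    uca: UcaSequence = group.uca  # type: ignore[assignment]
    seqs: list[str] = []
    for m in group.members:
        if not m.is_germline and m.sequence not in seqs:
            seqs.append(m.sequence)
    if uca.sequence in seqs:
        seqs.remove(uca.sequence)
    seqs.append(uca.sequence)
    if len(seqs) == 1:
        topo = nx.Graph()
        topo.add_node(0)
    else:
        topo = search_mp(seqs, max_exhaustive=max_exhaustive, seed=seed).topology
    return to_lineage_graph(topo, seqs, uca, group)


# ---------------------------------------------------------------------------
# export / import


def _newick(tree: LineageTree, node: str) -> str:
    d = tree.graph.nodes[node]
    comment = f"[&copy_count={d['copy_count']},is_inferred={'T' if d['is_inferred'] else 'F'}]"
    children = sorted(tree.graph.successors(node))
    label = f"{node}{comment}"
    if not children:
        return label
    parts = ",".join(
        f"{_newick(tree, c)}:{tree.graph.edges[node, c]['weight']}" for c in children
    )
    return f"({parts}){label}"


def export_tree(tree: LineageTree, path, fmt: str) -> None:
    """Write the lineage graph as newick, graphml or dot."""
    path = str(path)
    if fmt == "newick":
        with open(path, "w") as fh:
            fh.write(_newick(tree, tree.root) + ";\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for n, d in tree.graph.nodes(data=True):
            g.add_node(
                n,
                sequence=d["sequence"],
                copy_count=int(d["copy_count"]),
                compartments=json.dumps(dict(d["compartments"]), sort_keys=True),
                isotypes=json.dumps(dict(d["isotypes"]), sort_keys=True),
                is_germline=bool(d["is_germline"]),
                is_inferred=bool(d["is_inferred"]),
            )
        for u, v, d in tree.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]))
        nx.write_graphml(g, path)
    elif fmt == "dot":
        lines = ["digraph lineage {"]
        for n, d in sorted(tree.graph.nodes(data=True)):
            comps = ";".join(f"{k}:{v}" for k, v in sorted(d["compartments"].items()))
            isos = ";".join(f"{k}:{v}" for k, v in sorted(d["isotypes"].items()))
            lines.append(
                f'  "{n}" [copy_count={d["copy_count"]}, compartments="{comps}", '
                f'isotypes="{isos}", inferred={str(d["is_inferred"]).lower()}];'
            )
        for u, v, d in sorted(tree.graph.edges(data=True)):
            lines.append(f'  "{u}" -> "{v}" [label={d["weight"]}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown tree format: {fmt!r} (use newick, graphml or dot)")


def import_graphml(path) -> LineageTree:
    """Re-import a GraphML lineage tree written by :func:`export_tree`."""
    g = nx.read_graphml(str(path))
    out = nx.DiGraph()
    root = None
    for n, d in g.nodes(data=True):
        out.add_node(
            n,
            sequence=d["sequence"],
            copy_count=int(d["copy_count"]),
            compartments=Counter(json.loads(d["compartments"])),
            isotypes=Counter(json.loads(d["isotypes"])),
            is_germline=bool(d["is_germline"]),
            is_inferred=bool(d["is_inferred"]),
        )
        if d["is_germline"]:
            root = n
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, weight=int(d["weight"]))
    if root is None:
        raise ValueError("no germline root node in GraphML input")
    return LineageTree(graph=out, root=root)
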