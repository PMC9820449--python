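"""Clonal clustering and drop-in query tracing.

Two records can belong to the same clone only if their junctions have equal
length and their V and J gene sets (allele suffixes stripped) intersect.
Ambiguous multi-gene calls use set semantics with transitive closure: records
A and C fall in one partition whenever a chain of pairwise set overlaps
connects them, even if A and C share no gene directly.  Within a partition,
clones are single-linkage connected components of the <=-threshold relation
on normalized junction Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .airr_io import IgHRecord, RecordValidationError, Repertoire
from .distance import normalized_hamming


@dataclass
class CloneAssignment:
    """Result of clustering: sequence_id -> clone_id plus per-clone metadata."""

    assignment: dict[str, str] = field(default_factory=dict)
    clones: dict[str, list[str]] = field(default_factory=dict)
    partition_key: dict[str, tuple] = field(default_factory=dict)


@dataclass
class ClonotypeGroup:
    """The clone containing a traced query sequence, plus (later) its UCA."""

    clone_id: str
    members: list[IgHRecord]
    query_id: str | None = None
    uca: object | None = None  # UcaSequence, attached by the germline module

    def member_ids(self) -> list[str]:
        return [m.sequence_id for m in self.members]

    def non_query_members(self) -> list[IgHRecord]:
        return [m for m in self.members if m.sequence_id != self.query_id]


def merge_compartments(reps: list[Repertoire]) -> Repertoire:
    """Concatenate per-compartment repertoires of one subject.

    Compartment labels travel on the records; colliding sequence_ids are
    disambiguated with a ``<compartment>|`` prefix.
    """
    subjects = {r.subject for r in reps if r.subject}
    if len(subjects) > 1:
        raise ValueError(f"cannot merge repertoires from different subjects: {sorted(subjects)}")
    seen: dict[str, int] = {}
    for rep in reps:
        for rec in rep.records:
            seen[rec.sequence_id] = seen.get(rec.sequence_id, 0) + 1
    records: list[IgHRecord] = []
    for rep in reps:
        for rec in rep.records:
            rec = rec.copy()
            if not rec.compartment:
                rec = rec.copy(compartment=rep.compartment)
            if seen[rec.sequence_id] > 1:
                rec = rec.copy(sequence_id=f"{rec.compartment}|{rec.sequence_id}")
            records.append(rec)
    return Repertoire(records=records, subject=next(iter(subjects), ""), compartment="merged")


def _compatible(r1: IgHRecord, r2: IgHRecord) -> bool:
    return (
        len(r1.junction) == len(r2.junction)
        and bool(r1.v_genes & r2.v_genes)
        and bool(r1.j_genes & r2.j_genes)
    )


def _partitions(records: list[IgHRecord]) -> list[list[int]]:
    """Connected components of the gene/junction-length compatibility relation."""
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        by_len.setdefault(len(r.junction), []).append(i)
    for idxs in by_len.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                if _compatible(records[i], records[j]):
                    g.add_edge(i, j)
    return [sorted(c) for c in nx.connected_components(g)]


def _linkage_clusters(
    records: list[IgHRecord], idxs: list[int], threshold: float, linkage: str
) -> list[list[int]]:
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(idxs)
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                if normalized_hamming(records[i].junction, records[j].junction) <= threshold:
                    g.add_edge(i, j)
        return [sorted(c) for c in nx.connected_components(g)]
    if linkage == "complete":
        # naive agglomerative complete linkage; partitions are small
        clusters = [[i] for i in idxs]
        while True:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d = max(
                        normalized_hamming(records[i].junction, records[j].junction)
                        for i in clusters[a]
                        for j in clusters[b]
                    )
                    if d <= threshold and (best is None or d < best[0]):
                        best = (d, a, b)
            if best is None:
                return [sorted(c) for c in clusters]
            _, a, b = best
            clusters[a] = clusters[a] + clusters[b]
            del clusters[b]
    raise ValueError(f"unknown linkage: {linkage!r}")


def cluster_clones(
    rep: Repertoire, threshold: float, linkage: str = "single"
) -> CloneAssignment:
    """Assign every record to a clone at the given junction-distance threshold.

    Clone ids are ``<subject>_<k>`` with a deterministic order: partitions
    sorted by (junction length, V genes, J genes), clones within a partition
    by their smallest member sequence_id.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    records = list(rep.records)
    subject = rep.subject or "S"
    out = CloneAssignment()
    keyed = []
    for part in _partitions(records):
        v_genes = sorted(set().union(*(records[i].v_genes for i in part)))
        j_genes = sorted(set().union(*(records[i].j_genes for i in part)))
        key = (len(records[part[0]].junction), tuple(v_genes), tuple(j_genes))
        keyed.append((key, part))
    counter = 0
    for key, part in sorted(keyed, key=lambda kp: kp[0]):
        clusters = _linkage_clusters(records, part, threshold, linkage)
        clusters.sort(key=lambda c: min(records[i].sequence_id for i in c))
        for cluster in clusters:
            counter += 1
            clone_id = f"{subject}_{counter}"
            ids = [records[i].sequence_id for i in cluster]
            out.clones[clone_id] = ids
            out.partition_key[clone_id] = key
            for sid in ids:
                out.assignment[sid] = clone_id
    return out


def trace_query(
    query: IgHRecord, rep: Repertoire, threshold: float, linkage: str = "single"
) -> ClonotypeGroup:
    """Extract the clonotype group of a drop-in query sequence.

    The repertoire is pre-filtered to records that could share the query's
    partition (equal junction length, then the connected component of the
    gene-compatibility relation containing the query), the query is added,
    clones are clustered, and the query's clone is returned.  The pre-filter
    is a pure optimization: the result equals clustering the full repertoire
    with the query added and extracting its clone.
    """
    if not query.junction:
        raise RecordValidationError(f"{query.sequence_id}: query lacks a junction")
    if not query.v_call or not query.j_call:
        raise RecordValidationError(f"{query.sequence_id}: query lacks V/J calls")
    qid = query.sequence_id
    taken = {r.sequence_id for r in rep.records}
    if qid in taken:
        qid = f"query|{qid}"
        query = query.copy(sequence_id=qid)

    candidates = [r for r in rep.records if len(r.junction) == len(query.junction)]
    pool = [query] + candidates
    component_idx = next(part for part in _partitions(pool) if 0 in part)
    filtered = [pool[i] for i in component_idx]
    sub = Repertoire(records=filtered, subject=rep.subject, compartment=rep.compartment)
    assignment = cluster_clones(sub, threshold, linkage=linkage)
    clone_id = assignment.assignment[qid]
    member_ids = set(assignment.clones[clone_id])
    members = [r for r in filtered if r.sequence_id in member_ids]
    return ClonotypeGroup(clone_id=clone_id, members=members, query_id=qid)
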