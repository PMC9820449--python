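"""Per-lineage expansion, diversification and isotype summaries.

Expansion is measured in read copies (sum of duplicate_count per
compartment), diversification as the number of distinct V-region nucleotide
sequences, and class switching from the isotype multiset.  Germline rows,
inferred nodes and the drop-in query itself are excluded — the query is a
single-cell sequence, not a repertoire read.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clonotype import ClonotypeGroup

_UNSWITCHED = {"IgM", "IgD"}
_SWITCHED = {"IgG", "IgA", "IgE"}


@dataclass
class LineageSummary:
    """Three aligned tables: per-compartment counts, per-isotype counts, flags."""

    compartments: pd.DataFrame  # lineage, compartment, total_copies, distinct_sequences
    isotypes: pd.DataFrame  # lineage, isotype, total_copies
    flags: pd.DataFrame  # lineage, reached_memory, class_switched


def lineage_summary(groups: list[ClonotypeGroup], memory_label: str = "M") -> LineageSummary:
    """Summarize traced lineages per compartment and per isotype."""
    comp_rows, iso_rows, flag_rows = [], [], []
    for group in groups:
        members = [
            m
            for m in group.members
            if not m.is_germline and m.sequence_id != group.query_id
        ]
        if not members:
            continue
        per_comp: dict[str, tuple[int, set[str]]] = {}
        per_iso: dict[str, int] = {}
        for m in members:
            copies, seqs = per_comp.get(m.compartment, (0, set()))
            per_comp[m.compartment] = (copies + m.duplicate_count, seqs | {m.sequence})
            per_iso[m.isotype] = per_iso.get(m.isotype, 0) + m.duplicate_count
        for comp in sorted(per_comp):
            copies, seqs = per_comp[comp]
            comp_rows.append(
                {
                    "lineage": group.clone_id,
                    "compartment": comp,
                    "total_copies": copies,
                    "distinct_sequences": len(seqs),
                }
            )
        for iso in sorted(per_iso):
            iso_rows.append(
                {"lineage": group.clone_id, "isotype": iso, "total_copies": per_iso[iso]}
            )
        flag_rows.append(
            {
                "lineage": group.clone_id,
                "reached_memory": any(m.compartment == memory_label for m in members),
                "class_switched": any(m.isotype in _SWITCHED for m in members),
            }
        )
    return LineageSummary(
        compartments=pd.DataFrame(
            comp_rows, columns=["lineage", "compartment", "total_copies", "distinct_sequences"]
        ),
        isotypes=pd.DataFrame(iso_rows, columns=["lineage", "isotype", "total_copies"]),
        flags=pd.DataFrame(flag_rows, columns=["lineage", "reached_memory", "class_switched"]),
    )


def tracking_rates(
    queries: list[tuple[str, str, str]],
    groups: list[ClonotypeGroup],
    naive_labels: frozenset[str] = frozenset({"N"}),
) -> pd.DataFrame:
    """Fraction of queries with clonal relatives, per subject and reactivity label.

    ``queries`` rows are (query_id, subject, label) with label e.g. "PR/AR" or
    "NPR".  A query counts as tracked when its group contains at least one
    non-query repertoire member; as tracked-non-naive when such a member lies
    outside the naive compartments.
    """
    by_query: dict[str, ClonotypeGroup] = {g.query_id: g for g in groups if g.query_id}
    rows = []
    for (subject, label), sub in _group_pairs(queries):
        n = len(sub)
        tracked = 0
        non_naive = 0
        for qid, _, _ in sub:
            group = by_query.get(qid)
            relatives = [
                m for m in (group.non_query_members() if group else []) if not m.is_germline
            ]
            if relatives:
                tracked += 1
            if any(m.compartment not in naive_labels for m in relatives):
                non_naive += 1
        rows.append(
            {
                "subject": subject,
                "label": label,
                "n_queries": n,
                "frac_tracked": tracked / n,
                "frac_tracked_non_naive": non_naive / n,
            }
        )
    return pd.DataFrame(
        rows, columns=["subject", "label", "n_queries", "frac_tracked", "frac_tracked_non_naive"]
    )


def _group_pairs(queries):
    keys = []
    grouped: dict[tuple[str, str], list] = {}
    for q in queries:
        key = (q[1], q[2])
        if key not in grouped:
            grouped[key] = []
            keys.append(key)
        grouped[key].append(q)
    for key in keys:
        yield key, grouped[key]
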