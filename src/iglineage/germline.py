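"""Unmutated common ancestor (UCA) reconstruction with D-masking.

One germline is built per clone ("cloned" semantics): the clone-consensus V
and J genes are read from the members' calls, germline V covers the V region,
germline J the J region, and the junction interior between the germline V 3'
end and the germline J 5' start — N/P additions plus the D segment, whose
call is unreliable — is masked with ``N``.  The UCA lives in the members'
(FWR1-trimmed) coordinate space so it can root lineage trees directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .airr_io import GermlineReference, IgHRecord, gene_level
from .clonotype import ClonotypeGroup


@dataclass
class UcaSequence:
    """Clone germline with the junction interior masked.

    ``sequence`` has the same length/coordinates as the clone members'
    trimmed sequences; positions in [mask_start, mask_end) are ``N``.
    """

    sequence: str
    v_gene: str
    j_gene: str
    mask_start: int
    mask_end: int


def _majority_gene(groups: list[frozenset[str]]) -> str:
    votes: Counter[str] = Counter()
    for genes in groups:
        votes.update(genes)
    top = max(votes.values())
    return min(g for g, n in votes.items() if n == top)


def build_uca(group: ClonotypeGroup, ref: GermlineReference) -> UcaSequence:
    """Reconstruct the clone's closest unmutated common ancestor.

    V and J genes are the majority vote over member calls (tie: smallest gene
    name).  Mask boundaries come from the V-end/J-start annotations of the
    member with the highest duplicate_count (falling back to the junction
    interior when region annotations are absent).
    """
    members = [m for m in group.members if not m.is_germline]
    if not members:
        raise ValueError("cannot build a UCA for an empty clonotype group")
    lengths = {len(m.sequence) for m in members}
    if len(lengths) != 1:
        raise ValueError(f"clone members have irreconcilable sequence lengths: {sorted(lengths)}")
    length = lengths.pop()

    v_gene = _majority_gene([m.v_genes for m in members])
    j_gene = _majority_gene([m.j_genes for m in members])
    for gene in (v_gene, j_gene):
        if gene not in ref:
            raise KeyError(f"germline gene not found in reference: {gene!r}")

    anchor = sorted(members, key=lambda m: (-m.duplicate_count, m.sequence_id))[0]
    if anchor.v_end is not None and anchor.j_start is not None:
        mask_start, mask_end = anchor.v_end, anchor.j_start
    elif anchor.junction_start is not None:
        # no alignment columns: mask the full junction interior minus the
        # conserved codons is unknowable, so mask the whole junction
        mask_start, mask_end = anchor.junction_start, anchor.junction_end
    else:
        raise ValueError(
            f"{anchor.sequence_id}: need v_sequence_end/j_sequence_start or "
            "junction position annotations to place the D-mask"
        )

    g_v = ref.ungapped(v_gene)
    g_j = ref.ungapped(j_gene)
    v_gl_end = anchor.v_germline_end if anchor.v_germline_end is not None else len(g_v)
    j_gl_start = anchor.j_germline_start if anchor.j_germline_start is not None else 0
    v_len = mask_start
    j_len = length - mask_end
    v_start = v_gl_end - v_len
    if v_start < 0:
        raise ValueError(
            f"germline V segment {v_gene} too short for the clone's V region "
            f"({v_len} nt needed, alignment ends at {v_gl_end})"
        )
    if j_gl_start + j_len > len(g_j):
        raise ValueError(
            f"germline J segment {j_gene} too short for the clone's J region "
            f"({j_len} nt needed from offset {j_gl_start}, length {len(g_j)})"
        )
    sequence = g_v[v_start:v_gl_end] + "N" * (mask_end - mask_start) + g_j[j_gl_start : j_gl_start + j_len]
    return UcaSequence(
        sequence=sequence,
        v_gene=v_gene,
        j_gene=j_gene,
        mask_start=mask_start,
        mask_end=mask_end,
    )


def attach_uca(group: ClonotypeGroup, uca: UcaSequence) -> ClonotypeGroup:
    """Insert the UCA into the clonotype group (member list unchanged)."""
    members = [m for m in group.members if not m.is_germline]
    if members and len(uca.sequence) != len(members[0].sequence):
        raise ValueError(
            f"UCA length {len(uca.sequence)} incompatible with member length "
            f"{len(members[0].sequence)}"
        )
    group.uca = uca
    return group


def uca_record(group: ClonotypeGroup) -> IgHRecord:
    """The attached UCA as an extra AIRR row (flagged is_germline)."""
    if group.uca is None:
        raise ValueError("group has no UCA attached")
    uca: UcaSequence = group.uca  # type: ignore[assignment]
    return IgHRecord(
        sequence_id=f"{group.clone_id}_germline",
        sequence=uca.sequence,
        v_call=frozenset({uca.v_gene}),
        j_call=frozenset({uca.j_gene}),
        junction="",
        productive=True,
        duplicate_count=0,
        isotype="unknown",
        compartment="germline",
        v_end=uca.mask_start,
        j_start=uca.mask_end,
        is_germline=True,
    )
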