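"""Repertoire cleaning: FWR1 trimming, identical-sequence merging, low-copy
error collapsing and the productive filter.

The pipeline order is fixed: trim -> merge -> collapse -> productive filter.
Collapsing absorbs presumed RT/PCR/sequencing error variants: a record with
fewer than ``copy_min`` copies whose sequence lies within Hamming distance
``max_dist`` of a high-copy record donates its count to that record; low-copy
records with no eligible partner are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .airr_io import IgHRecord, Repertoire

# IMGT unique numbering: FR1 spans codons 1-26, i.e. gapped nucleotide
# positions 1..78; CDR1 starts at codon 27 (gapped position 79).
_IMGT_FR1_GAPPED_LEN = 78


class MissingRegionError(ValueError):
    """Raised when neither region columns nor an IMGT-gapped alignment allow
    locating the CDR1 start; supply cdr1_start or sequence_alignment."""


@dataclass
class CollapseReport:
    """Accounting of a :func:`collapse_low_copy` run.

    Every input record appears exactly once across the retained set,
    ``absorbed`` and ``discarded``.
    """

    retained: int = 0
    absorbed: list[tuple[str, str, int, int]] = field(default_factory=list)
    discarded: list[str] = field(default_factory=list)


def _shift(value: int | None, offset: int) -> int | None:
    return None if value is None else value - offset


def trim_to_cdr1_fwr4(rec: IgHRecord) -> IgHRecord:
    """Remove the FWR1 region, keeping CDR1 through FWR4.

    The trim point is ``cdr1_start`` when annotated, otherwise derived from
    the IMGT-gapped ``sequence_alignment`` (CDR1 begins at codon 27, gapped
    nucleotide position 79).  Junction content is unchanged; all offsets are
    re-expressed relative to the trimmed sequence.
    """
    if rec.cdr1_start is not None:
        t = rec.cdr1_start
    elif rec.sequence_alignment:
        t = sum(1 for c in rec.sequence_alignment[:_IMGT_FR1_GAPPED_LEN] if c != ".")
    else:
        raise MissingRegionError(
            f"{rec.sequence_id}: cannot locate CDR1 start; supply cdr1_start "
            "region column or an IMGT-gapped sequence_alignment"
        )
    if t == 0:
        return rec.copy()
    alignment = rec.sequence_alignment[_IMGT_FR1_GAPPED_LEN:] if rec.sequence_alignment else ""
    return rec.copy(
        sequence=rec.sequence[t:],
        sequence_alignment=alignment,
        cdr1_start=0,
        junction_start=_shift(rec.junction_start, t),
        v_end=_shift(rec.v_end, t),
        j_start=_shift(rec.j_start, t),
    )


def merge_identical(rep: Repertoire) -> Repertoire:
    """Merge records with identical nucleotide sequence, summing copy counts.

    Records identical in sequence but differing in isotype stay separate
    (isotype is biological signal); the representative record is the first
    occurrence and total duplicate_count is conserved.
    """
    merged: dict[tuple[str, str, str], IgHRecord] = {}
    order: list[tuple[str, str, str]] = []
    for rec in rep.records:
        key = (rec.sequence, rec.isotype, rec.compartment)
        if key in merged:
            prev = merged[key]
            merged[key] = prev.copy(duplicate_count=prev.duplicate_count + rec.duplicate_count)
        else:
            merged[key] = rec.copy()
            order.append(key)
    return Repertoire(records=[merged[k] for k in order], subject=rep.subject, compartment=rep.compartment)


def _plain_hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def collapse_low_copy(
    rep: Repertoire,
    copy_min: int = 5,
    max_dist: int = 1,
    junction_only: bool = False,
) -> tuple[Repertoire, CollapseReport]:
    """Absorb low-copy error variants into their high-copy neighbors.

    Records with ``duplicate_count < copy_min`` form the low-copy pool.  Each
    donates its full count to exactly one high-copy record at Hamming
    distance <= ``max_dist`` (tie-break: smallest distance, then largest
    duplicate_count, then smallest sequence_id); the rest are discarded.
    Unequal-length sequences are never collapse partners.  With
    ``junction_only`` distances are computed on junction strings instead of
    the full retained sequence.
    """
    if copy_min < 1:
        raise ValueError("copy_min must be >= 1")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")

    def seq_of(r: IgHRecord) -> str:
        return r.junction if junction_only else r.sequence

    high = [r.copy() for r in rep.records if r.duplicate_count >= copy_min]
    low = [r for r in rep.records if r.duplicate_count < copy_min]
    report = CollapseReport(retained=len(high))
    for lo in low:
        best: tuple[int, int, str] | None = None
        best_rec: IgHRecord | None = None
        ls = seq_of(lo)
        for hi in high:
            hs = seq_of(hi)
            if len(hs) != len(ls):
                continue
            d = _plain_hamming(ls, hs)
            if d > max_dist:
                continue
            key = (d, -hi.duplicate_count, hi.sequence_id)
            if best is None or key < best:
                best, best_rec = key, hi
        if best_rec is None:
            report.discarded.append(lo.sequence_id)
        else:
            report.absorbed.append((lo.sequence_id, best_rec.sequence_id, best[0], lo.duplicate_count))
            best_rec.duplicate_count += lo.duplicate_count
    out = Repertoire(records=high, subject=rep.subject, compartment=rep.compartment)
    return out, report


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep only productive rearrangements, preserving order."""
    return Repertoire(
        records=[r.copy() for r in rep.records if r.productive],
        subject=rep.subject,
        compartment=rep.compartment,
    )


def preprocess_repertoire(
    rep: Repertoire, copy_min: int = 5, max_dist: int = 1
) -> tuple[Repertoire, CollapseReport]:
    """Full cleaning pipeline: trim -> merge -> collapse -> productive filter."""
    trimmed = Repertoire(
        records=[trim_to_cdr1_fwr4(r) for r in rep.records],
        subject=rep.subject,
        compartment=rep.compartment,
    )
    merged = merge_identical(trimmed)
    collapsed, report = collapse_low_copy(merged, copy_min=copy_min, max_dist=max_dist)
    return filter_productive(collapsed), report
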