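"""AIRR Rearrangement TSV and germline FASTA input/output.

The on-disk interchange format is the community-standard AIRR Rearrangement
TSV (MiAIRR column names, 1-based closed coordinate intervals, ``T``/``F``
booleans, comma-separated multi-gene calls).  Internally every coordinate is
a 0-based half-open offset into ``sequence``; the conversion happens here and
nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

ISOTYPES = ("IgM", "IgD", "IgG", "IgA", "IgE", "unknown")

#: Constant-region call prefixes mapped onto isotype labels.
_C_CALL_ISOTYPE = {
    "IGHM": "IgM",
    "IGHD": "IgD",
    "IGHG": "IgG",
    "IGHA": "IgA",
    "IGHE": "IgE",
}

_TRUE = {"T", "TRUE", "true", "True", "1"}
_FALSE = {"F", "FALSE", "false", "False", "0", ""}

REQUIRED_COLUMNS = ("sequence_id", "sequence", "v_call", "j_call", "junction", "productive")


class SchemaError(ValueError):
    """The input table does not carry a required AIRR column."""


class RecordValidationError(ValueError):
    """A row violates an AIRR record invariant (names the sequence_id)."""


def gene_level(allele: str) -> str:
    """Strip the IMGT allele suffix: ``IGHV1-2*02`` -> ``IGHV1-2``."""
    return allele.split("*", 1)[0]


def _parse_call(value: str) -> frozenset[str]:
    return frozenset(v.strip() for v in value.split(",") if v.strip())


def _fmt_call(calls: frozenset[str]) -> str:
    return ",".join(sorted(calls))


@dataclass
class IgHRecord:
    """One annotated heavy-chain rearrangement.

    Offsets (``cdr1_start``, ``junction_start``, ``v_end``, ``j_start``) are
    0-based half-open positions within ``sequence``; germline offsets refer to
    the ungapped germline segment.  Any of them may be ``None`` when the
    upstream annotation did not provide them.
    """

    sequence_id: str
    sequence: str
    v_call: frozenset[str]
    j_call: frozenset[str]
    junction: str
    productive: bool
    d_call: frozenset[str] = frozenset()
    duplicate_count: int = 1
    isotype: str = "unknown"
    compartment: str = ""
    sequence_alignment: str = ""
    cdr1_start: int | None = None
    junction_start: int | None = None
    v_end: int | None = None
    j_start: int | None = None
    v_germline_end: int | None = None
    j_germline_start: int | None = None
    is_germline: bool = False

    def __post_init__(self) -> None:
        if self.duplicate_count < 1 and not self.is_germline:
            raise RecordValidationError(
                f"{self.sequence_id}: duplicate_count must be >= 1"
            )
        if not self.v_call or not self.j_call:
            raise RecordValidationError(f"{self.sequence_id}: v_call and j_call must be non-empty")
        if self.junction_start is None and self.junction:
            pos = self.sequence.find(self.junction)
            if pos >= 0:
                self.junction_start = pos
        if self.junction_start is not None and self.junction:
            end = self.junction_start + len(self.junction)
            if self.sequence[self.junction_start : end] != self.junction:
                raise RecordValidationError(
                    f"{self.sequence_id}: junction is not at the stated position in sequence"
                )

    @property
    def junction_length(self) -> int:
        return len(self.junction)

    @property
    def junction_end(self) -> int | None:
        if self.junction_start is None:
            return None
        return self.junction_start + len(self.junction)

    @property
    def v_genes(self) -> frozenset[str]:
        return frozenset(gene_level(a) for a in self.v_call)

    @property
    def j_genes(self) -> frozenset[str]:
        return frozenset(gene_level(a) for a in self.j_call)

    def copy(self, **changes) -> "IgHRecord":
        return dataclasses.replace(self, **changes)


@dataclass
class Repertoire:
    """Ordered collection of IgH records from one subject/compartment."""

    records: list[IgHRecord] = field(default_factory=list)
    subject: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        ids = [r.sequence_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise RecordValidationError(f"duplicate sequence_id in repertoire: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IgHRecord]:
        return iter(self.records)

    def total_copies(self) -> int:
        return sum(r.duplicate_count for r in self.records)


class GermlineReference:
    """Allele name -> IMGT-gapped germline sequence, per segment class (V/D/J)."""

    def __init__(self, alleles: Mapping[str, str]):
        self._alleles = dict(alleles)
        # gene -> sorted alleles, for gene-level resolution
        self._by_gene: dict[str, list[str]] = {}
        for name in sorted(self._alleles):
            self._by_gene.setdefault(gene_level(name), []).append(name)

    def __len__(self) -> int:
        return len(self._alleles)

    def __contains__(self, name: str) -> bool:
        return name in self._alleles or name in self._by_gene

    def alleles(self) -> dict[str, str]:
        return dict(self._alleles)

    def resolve(self, name: str) -> str:
        """Resolve a gene- or allele-level name to a concrete allele name.

        A gene-level name (no ``*``) resolves to its lexicographically first
        allele, the IMGT convention for the reference allele (``*01``).
        """
        if name in self._alleles:
            return name
        if name in self._by_gene:
            return self._by_gene[name][0]
        raise KeyError(f"germline segment not found in reference: {name!r}")

    def gapped(self, name: str) -> str:
        return self._alleles[self.resolve(name)]

    def ungapped(self, name: str) -> str:
        return self.gapped(name).replace(".", "")


def read_airr(path, compartment: str = "", subject: str = "") -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Required columns: sequence_id, sequence, v_call, j_call, junction,
    productive.  Optional: d_call, duplicate_count (default 1), isotype or
    c_call, compartment, sequence_alignment, junction_length (validated),
    cdr1_start, junction_start, v_sequence_end, j_sequence_start,
    v_germline_end, j_germline_start, is_germline.  All file coordinates are
    1-based closed intervals per the AIRR standard.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required AIRR column: {col!r}")

    def opt(row, col):
        if col in df.columns and row[col] != "":
            return row[col]
        return None

    def opt_pos(row, col):
        """1-based closed start -> 0-based offset."""
        v = opt(row, col)
        return None if v is None else int(v) - 1

    def opt_end(row, col):
        """1-based closed end -> 0-based half-open end."""
        v = opt(row, col)
        return None if v is None else int(v)

    records: list[IgHRecord] = []
    for _, row in df.iterrows():
        sid = row["sequence_id"]
        prod_raw = row["productive"]
        if prod_raw in _TRUE:
            productive = True
        elif prod_raw in _FALSE:
            productive = False
        else:
            raise RecordValidationError(f"{sid}: unparseable productive value {prod_raw!r}")
        junction = row["junction"]
        jl = opt(row, "junction_length")
        if jl is not None and int(jl) != len(junction):
            raise RecordValidationError(
                f"{sid}: junction_length {jl} does not match junction string of length {len(junction)}"
            )
        isotype = opt(row, "isotype")
        if isotype is None:
            c_call = opt(row, "c_call")
            if c_call is not None:
                isotype = next(
                    (iso for pre, iso in _C_CALL_ISOTYPE.items() if c_call.upper().startswith(pre)),
                    "unknown",
                )
            else:
                isotype = "unknown"
        rec = IgHRecord(
            sequence_id=sid,
            sequence=row["sequence"],
            v_call=_parse_call(row["v_call"]),
            d_call=_parse_call(row["d_call"]) if "d_call" in df.columns else frozenset(),
            j_call=_parse_call(row["j_call"]),
            junction=junction,
            productive=productive,
            duplicate_count=int(opt(row, "duplicate_count") or 1),
            isotype=isotype,
            compartment=opt(row, "compartment") or compartment,
            sequence_alignment=opt(row, "sequence_alignment") or "",
            cdr1_start=opt_pos(row, "cdr1_start"),
            junction_start=opt_pos(row, "junction_start"),
            v_end=opt_end(row, "v_sequence_end"),
            j_start=opt_pos(row, "j_sequence_start"),
            v_germline_end=opt_end(row, "v_germline_end"),
            j_germline_start=opt_pos(row, "j_germline_start"),
            is_germline=(opt(row, "is_germline") in _TRUE),
        )
        records.append(rec)
    return Repertoire(records=records, subject=subject, compartment=compartment)


_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_length",
    "productive",
    "duplicate_count",
    "isotype",
    "compartment",
    "sequence_alignment",
    "cdr1_start",
    "junction_start",
    "v_sequence_end",
    "j_sequence_start",
    "v_germline_end",
    "j_germline_start",
    "is_germline",
]


def write_airr(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR TSV; ``read_airr(write_airr(rep))`` round-trips.

    Gene call sets are serialized in sorted order so re-serialization is
    byte-identical.
    """
    rows = []
    for r in rep.records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "sequence": r.sequence,
                "v_call": _fmt_call(r.v_call),
                "d_call": _fmt_call(r.d_call),
                "j_call": _fmt_call(r.j_call),
                "junction": r.junction,
                "junction_length": len(r.junction),
                "productive": "T" if r.productive else "F",
                "duplicate_count": r.duplicate_count,
                "isotype": r.isotype,
                "compartment": r.compartment,
                "sequence_alignment": r.sequence_alignment,
                "cdr1_start": "" if r.cdr1_start is None else r.cdr1_start + 1,
                "junction_start": "" if r.junction_start is None else r.junction_start + 1,
                "v_sequence_end": "" if r.v_end is None else r.v_end,
                "j_sequence_start": "" if r.j_start is None else r.j_start + 1,
                "v_germline_end": "" if r.v_germline_end is None else r.v_germline_end,
                "j_germline_start": "" if r.j_germline_start is None else r.j_germline_start + 1,
                "is_germline": "T" if r.is_germline else "F",
            }
        )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_germline_fasta(paths: Iterable | str) -> GermlineReference:
    """Read germline V/D/J FASTA file(s) into a :class:`GermlineReference`.

    The allele name is the first ``|``-separated token of the header (IMGT
    convention).  Gap characters ``.`` are preserved.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "read_text"):
        paths = [paths]
    alleles: dict[str, str] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id.split("|")[0]
            if name in alleles:
                raise ValueError(f"duplicate germline allele name: {name!r}")
            alleles[name] = str(rec.seq).upper()
    if not alleles:
        raise ValueError("no germline sequences found in input FASTA")
    return GermlineReference(alleles)
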