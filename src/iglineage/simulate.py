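"""Synthetic clonally-structured IgH repertoires with known ground truth.

Each clone starts from a recombined germline (random V/D/J choice, small 3'/5'
exonuclease trimming, random N additions at both junctions) and evolves along
a random branching genealogy accumulating somatic point mutations.  Members
advance through B-cell compartments in root-to-leaf order (naive before
memory) and switch isotype irreversibly (IgM/IgD -> IgG/IgA/IgE).  Low-copy
error variants one mismatch away from true reads emulate RT/PCR/sequencing
noise.  Junctions of distinct clones sharing a partition are kept above a
distance floor so the planted within/between bimodality is real and
verifiable via :func:`distance_separation_report`.

SHM is uniform per site (no hot/cold spots) and indel-free; both choices
keep the fixture within the pipeline's Hamming-metric assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airr_io import GermlineReference, IgHRecord, Repertoire
from .distance import normalized_hamming

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the repertoire generator.

    Defaults describe a desk-scale subject: 30 clones across three sorted
    compartments, geometric-ish clone sizes around 4 members, ~2 point
    mutations per branch with at most one falling in the junction (junctions
    are conserved within clones), true read counts at or above the collapse
    cutoff of 5, and a 0.25 chance per true read of spawning a 1-mismatch
    low-copy artifact.
    """

    seed: int
    n_clones: int = 30
    members_per_clone_mean: float = 4.0
    shm_per_generation: float = 2.0
    max_junction_mut_per_branch: int = 1
    between_floor: float = 0.25
    copy_count_min: int = 5
    copy_count_max: int = 60
    error_variant_rate: float = 0.25
    error_copy_max: int = 4
    nonproductive_rate: float = 0.03
    compartment_advance_p: float = 0.45
    isotype_switch_p: float = 0.3
    n_addition_min: int = 4
    n_addition_max: int = 10
    compartments: tuple[str, ...] = ("N", "A", "M")
    subject: str = "S1"

    def validate(self) -> None:
        probs = {
            "error_variant_rate": self.error_variant_rate,
            "nonproductive_rate": self.nonproductive_rate,
            "compartment_advance_p": self.compartment_advance_p,
            "isotype_switch_p": self.isotype_switch_p,
            "between_floor": self.between_floor,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.copy_count_min < 1 or self.copy_count_max < self.copy_count_min:
            raise ValueError("invalid copy count range")
        if self.error_copy_max < 1:
            raise ValueError("error_copy_max must be >= 1")


@dataclass
class SimTruth:
    """Ground truth: one row per emitted record plus per-clone germline facts."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    clones: pd.DataFrame = field(default_factory=pd.DataFrame)


_RECORD_COLS = [
    "sequence_id",
    "clone_id",
    "parent_id",
    "is_error_variant",
    "compartment",
    "isotype",
    "productive",
    "duplicate_count",
    "junction",
    "sequence",
]

_CLONE_COLS = [
    "clone_id",
    "v_allele",
    "d_allele",
    "j_allele",
    "germline_full",
    "germline_trimmed",
    "mask_start_trimmed",
    "mask_end_trimmed",
    "cdr1_start",
]


def make_toy_reference(
    seed: int = 0,
    n_v: int = 4,
    n_d: int = 3,
    n_j: int = 4,
    v_len: int = 102,
    d_len: int = 18,
    j_len: int = 45,
) -> GermlineReference:
    """Random toy germline V/D/J reference (ungapped, one allele per gene)."""
    rng = np.random.default_rng(seed)
    alleles: dict[str, str] = {}
    for prefix, n, length in (("IGHV", n_v, v_len), ("IGHD", n_d, d_len), ("IGHJ", n_j, j_len)):
        for i in range(1, n + 1):
            alleles[f"{prefix}{i}-1*01"] = "".join(rng.choice(_BASES, size=length))
    return GermlineReference(alleles)


FWR1_LEN = 30  #: length of the simulated FWR1 region (trimmed by preprocessing)
_JUNCTION_V_NT = 6  #: germline V nucleotides inside the junction (conserved Cys side)
_JUNCTION_J_NT = 6  #: germline J nucleotides inside the junction


def _mutate(rng, seq: str, n_mut: int, junction_span: tuple[int, int], max_junction: int) -> str:
    chars = list(seq)
    js, je = junction_span
    positions: list[int] = []
    junction_hits = 0
    guard = 0
    while len(positions) < n_mut and guard < 200:
        guard += 1
        p = int(rng.integers(FWR1_LEN, len(chars)))  # FWR1 is trimmed anyway
        if p in positions:
            continue
        in_junction = js <= p < je
        if in_junction and junction_hits >= max_junction:
            continue
        positions.append(p)
        junction_hits += int(in_junction)
    for p in positions:
        old = chars[p]
        chars[p] = str(rng.choice([b for b in "ACGT" if b != old]))
    return "".join(chars)


def simulate_repertoire(
    config: SimConfig, ref: GermlineReference
) -> tuple[list[Repertoire], SimTruth]:
    """Generate per-compartment repertoires plus ground truth.

    Emitted records are untrimmed (FWR1 present) and carry the AIRR region
    and germline-alignment annotations the pipeline consumes.  Deterministic
    given (config.seed, ref).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    v_names = sorted(n for n in ref.alleles() if n.startswith("IGHV"))
    d_names = sorted(n for n in ref.alleles() if n.startswith("IGHD"))
    j_names = sorted(n for n in ref.alleles() if n.startswith("IGHJ"))
    if len(v_names) < 3 or len(d_names) < 2 or len(j_names) < 3:
        raise ValueError("toy reference needs >=3 V, >=2 D and >=3 J segments")

    clone_rows = []
    record_rows = []
    per_comp: dict[str, list[IgHRecord]] = {c: [] for c in config.compartments}
    existing_junctions: list[tuple[str, str, str]] = []  # (v_gene, j_gene, junction)

    for k in range(1, config.n_clones + 1):
        clone_id = f"clone{k:03d}"
        for _attempt in range(60):
            v_allele = str(rng.choice(v_names))
            d_allele = str(rng.choice(d_names))
            j_allele = str(rng.choice(j_names))
            v_seq = ref.ungapped(v_allele)
            d_seq = ref.ungapped(d_allele)
            j_seq = ref.ungapped(j_allele)
            v_trunc = int(rng.integers(0, 3))
            j_trunc = int(rng.integers(0, 3))
            d5 = int(rng.integers(0, 3))
            d3 = int(rng.integers(0, 3))
            n1 = "".join(rng.choice(_BASES, size=int(rng.integers(config.n_addition_min, config.n_addition_max + 1))))
            n2 = "".join(rng.choice(_BASES, size=int(rng.integers(config.n_addition_min, config.n_addition_max + 1))))
            v_part = v_seq[: len(v_seq) - v_trunc]
            d_part = d_seq[d5 : len(d_seq) - d3]
            j_part = j_seq[j_trunc:]
            germline_full = v_part + n1 + d_part + n2 + j_part
            v_end_full = len(v_part)
            j_start_full = len(v_part) + len(n1) + len(d_part) + len(n2)
            junction_start_full = v_end_full - _JUNCTION_V_NT
            junction_end_full = j_start_full + _JUNCTION_J_NT
            junction = germline_full[junction_start_full:junction_end_full]
            # keep clones sharing a (V, J, length) partition apart in junction space
            clash = False
            for (ev, ej, ejunc) in existing_junctions:
                if len(ejunc) == len(junction) and ev == v_allele and ej == j_allele:
                    if normalized_hamming(ejunc, junction) < config.between_floor:
                        clash = True
                        break
            if not clash:
                break
        existing_junctions.append((v_allele, j_allele, junction))

        clone_rows.append(
            {
                "clone_id": clone_id,
                "v_allele": v_allele,
                "d_allele": d_allele,
                "j_allele": j_allele,
                "germline_full": germline_full,
                "germline_trimmed": germline_full[FWR1_LEN:],
                "mask_start_trimmed": v_end_full - FWR1_LEN,
                "mask_end_trimmed": j_start_full - FWR1_LEN,
                "cdr1_start": FWR1_LEN,
            }
        )

        n_members = max(1, int(rng.poisson(config.members_per_clone_mean)))
        members: list[dict] = []
        for m_idx in range(n_members):
            sid = f"{clone_id}_m{m_idx:02d}"
            if m_idx == 0:
                seq = germline_full
                parent_id = ""
                comp_idx = 0
                isotype = "IgM"
                productive = True
            else:
                parent = members[int(rng.integers(0, len(members)))]
                n_mut = max(1, int(rng.poisson(config.shm_per_generation)))
                seq = _mutate(
                    rng,
                    parent["sequence"],
                    n_mut,
                    (junction_start_full, junction_end_full),
                    config.max_junction_mut_per_branch,
                )
                parent_id = parent["sequence_id"]
                comp_idx = parent["comp_idx"]
                if comp_idx < len(config.compartments) - 1 and rng.random() < config.compartment_advance_p:
                    comp_idx += 1
                isotype = parent["isotype"]
                if isotype in ("IgM", "IgD") and rng.random() < config.isotype_switch_p:
                    isotype = str(rng.choice(["IgG", "IgA", "IgE"], p=[0.7, 0.25, 0.05]))
                productive = True
            members.append(
                {
                    "sequence_id": sid,
                    "sequence": seq,
                    "parent_id": parent_id,
                    "comp_idx": comp_idx,
                    "isotype": isotype,
                    "productive": productive,
                    "duplicate_count": int(rng.integers(config.copy_count_min, config.copy_count_max + 1)),
                    "is_error_variant": False,
                }
            )
        # low-copy 1-mismatch artifacts of true reads
        artifacts: list[dict] = []
        for mem in members:
            if rng.random() < config.error_variant_rate:
                var = _mutate(rng, mem["sequence"], 1, (junction_start_full, junction_end_full), 1)
                artifacts.append(
                    {
                        "sequence_id": mem["sequence_id"] + "_err",
                        "sequence": var,
                        "parent_id": mem["sequence_id"],
                        "comp_idx": mem["comp_idx"],
                        "isotype": mem["isotype"],
                        "productive": mem["productive"],
                        "duplicate_count": int(rng.integers(1, config.error_copy_max + 1)),
                        "is_error_variant": True,
                    }
                )

        for row in members + artifacts:
            compartment = config.compartments[row["comp_idx"]]
            seq = row["sequence"]
            junction_now = seq[junction_start_full:junction_end_full]
            rec = IgHRecord(
                sequence_id=row["sequence_id"],
                sequence=seq,
                v_call=frozenset({v_allele}),
                d_call=frozenset({d_allele}),
                j_call=frozenset({j_allele}),
                junction=junction_now,
                productive=row["productive"],
                duplicate_count=row["duplicate_count"],
                isotype=row["isotype"],
                compartment=compartment,
                cdr1_start=FWR1_LEN,
                junction_start=junction_start_full,
                v_end=v_end_full,
                j_start=j_start_full,
                v_germline_end=len(v_seq) - v_trunc,
                j_germline_start=j_trunc,
            )
            per_comp[compartment].append(rec)
            record_rows.append(
                {
                    "sequence_id": row["sequence_id"],
                    "clone_id": clone_id,
                    "parent_id": row["parent_id"],
                    "is_error_variant": row["is_error_variant"],
                    "compartment": compartment,
                    "isotype": row["isotype"],
                    "productive": row["productive"],
                    "duplicate_count": row["duplicate_count"],
                    "junction": junction_now,
                    "sequence": seq,
                }
            )

    # non-productive reads are standalone frameshifted rearrangements, not
    # SHM'd members of expanding clones; they survive collapsing (high copy)
    # and exercise the productive filter at the end of preprocessing
    n_junk = int(round(config.nonproductive_rate * len(record_rows)))
    for k in range(1, n_junk + 1):
        v_allele = str(rng.choice(v_names))
        j_allele = str(rng.choice(j_names))
        v_seq = ref.ungapped(v_allele)
        j_seq = ref.ungapped(j_allele)
        n_region = "".join(rng.choice(_BASES, size=int(rng.integers(10, 25))))
        seq = v_seq + n_region + j_seq
        v_end_full = len(v_seq)
        j_start_full = len(v_seq) + len(n_region)
        junction_start_full = v_end_full - _JUNCTION_V_NT
        junction_now = seq[junction_start_full : j_start_full + _JUNCTION_J_NT]
        compartment = str(rng.choice(config.compartments))
        sid = f"junk{k:03d}"
        rec = IgHRecord(
            sequence_id=sid,
            sequence=seq,
            v_call=frozenset({v_allele}),
            j_call=frozenset({j_allele}),
            junction=junction_now,
            productive=False,
            duplicate_count=int(rng.integers(config.copy_count_min, config.copy_count_max + 1)),
            isotype="IgM",
            compartment=compartment,
            cdr1_start=FWR1_LEN,
            junction_start=junction_start_full,
            v_end=v_end_full,
            j_start=j_start_full,
            v_germline_end=len(v_seq),
            j_germline_start=0,
        )
        per_comp[compartment].append(rec)
        record_rows.append(
            {
                "sequence_id": sid,
                "clone_id": f"junk{k:03d}",
                "parent_id": "",
                "is_error_variant": False,
                "compartment": compartment,
                "isotype": "IgM",
                "productive": False,
                "duplicate_count": rec.duplicate_count,
                "junction": junction_now,
                "sequence": seq,
            }
        )

    reps = [
        Repertoire(records=per_comp[c], subject=config.subject, compartment=c)
        for c in config.compartments
    ]
    truth = SimTruth(
        records=pd.DataFrame(record_rows, columns=_RECORD_COLS),
        clones=pd.DataFrame(clone_rows, columns=_CLONE_COLS),
    )
    return reps, truth


def distance_separation_report(
    truth: SimTruth, reps: list[Repertoire]
) -> tuple[float, float | None]:
    """(max within-clone, min between-clone) normalized junction distance.

    Between-clone distances are taken over partition-compatible pairs only
    (equal junction length, shared V and J gene); ``None`` when no such
    cross-clone pair exists.
    """
    clone_of = dict(zip(truth.records["sequence_id"], truth.records["clone_id"]))
    recs = [r for rep in reps for r in rep.records]
    within_max = 0.0
    between_min: float | None = None
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if len(a.junction) != len(b.junction):
                continue
            same = clone_of[a.sequence_id] == clone_of[b.sequence_id]
            if same:
                within_max = max(within_max, normalized_hamming(a.junction, b.junction))
            elif a.v_genes & b.v_genes and a.j_genes & b.j_genes:
                d = normalized_hamming(a.junction, b.junction)
                between_min = d if between_min is None else min(between_min, d)
    return within_max, between_min
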