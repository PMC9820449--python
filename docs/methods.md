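# Methods

## Scope and assumptions

`iglineage` operates on *annotated* IgH rearrangements: V/D/J calls,
junction and region boundaries are taken from an upstream annotator (an
IMGT-style aligner) via AIRR Rearrangement TSV. No re-annotation or
alignment is performed. All sequence comparison is Hamming-based and
therefore assumes indel-free data within a clone; SHM indels (roughly one
per 10^4 nucleotides in vivo) are outside the model, and sequences of
unequal length are simply never compared.

Coordinates follow the AIRR convention on disk (1-based closed intervals)
and are 0-based half-open in memory; the conversion happens only in
`airr_io`.

## Preprocessing

The cleaning order is fixed: **trim → merge → collapse → productive
filter**.

- *Trimming* removes FWR1 and keeps CDR1–FWR4. The trim point is the
  annotated `cdr1_start`, or, failing that, the count of non-gap characters
  in the first 78 positions of the IMGT-gapped alignment (FR1 = codons
  1–26; CDR1 begins at codon 27, gapped nucleotide position 79).
- *Merging* unifies records with identical trimmed sequence, summing
  `duplicate_count`. Records identical in sequence but differing in isotype
  are kept separate: isotype is biological signal consumed by the lineage
  statistics, and counts are summed only within isotype.
- *Collapsing* splits the library at `copy_min` (default 5) copies. Each
  low-copy record at Hamming distance ≤ `max_dist` (default 1) of a
  high-copy record transfers its full count to exactly one partner —
  tie-break: smallest distance, then largest copy count, then smallest
  sequence id, i.e. the most plausible error source — and the remaining
  low-copy pool is discarded. Collapsing runs per input library (sequencing
  errors are library-specific), before any cross-compartment merge, and is
  idempotent: after one pass no low-copy records remain. Distances are
  computed on the full retained sequence; a `junction_only` flag is
  available. Low↔low merging is deliberately not performed.
- The *productive filter* runs last, on the retained high-copy pool.

## Distance threshold

Distance-to-nearest is computed on junction sequences — the same strings
that clustering later compares, so threshold and clustering share one
metric space; a full-sequence mode exists behind a flag. Two records are
comparable when junction lengths are equal and their gene-level V and J
call sets intersect; a record with ambiguous calls takes the minimum over
all partitions its calls allow. The distance is mismatches/length with any
non-ACGT symbol matching everything. Note this wildcard rule makes the
function a pseudometric only on plain nucleotide strings; `N` breaks the
triangle inequality by construction.

The histogram uses bins of width 0.01 whose *centers* lie on the 0.00,
0.01, … grid, so a detected threshold is always a round fraction.
Smoothing is a centered moving average over 5 bins, truncated at the edges.
The first peak is the first bin rising above both neighbours with at least
1% of the total count (the noise floor suppresses single-count blips on
sparse histograms). The threshold is the center of the first bin after the
peak at which the smoothed series has *stopped declining*, read as
s[j+1] ≥ s[j] (`variant="stop"`, the default): at a strict inter-mode
minimum this fires exactly at the valley, and on a histogram whose tail
decays to zero with no second mode it fires where the tail flattens — the
situation in which valley-finding methods fail. The alternative reading
s[j] ≥ s[j−1] (`variant="next"`) fires one bin later at strict minima and
is kept as a documented option. If the series declines monotonically to the
last bin, detection fails loudly and a manual threshold must be supplied.

By default the threshold is detected once on the merged multi-compartment
subject repertoire (more distances, stabler histogram); per-compartment
detection is a caller choice.

## Clonotype clustering and tracing

Partition compatibility is: equal junction length AND intersecting
gene-level V sets AND intersecting gene-level J sets, closed transitively
(records A and C sharing no gene still co-partition when a record B
overlaps both — multi-gene "set" semantics). Within a partition, clones are
single-linkage connected components of normalized junction Hamming
distance ≤ threshold; complete linkage is available behind a flag. Clone
ids are `<subject>_<k>` with a deterministic order (partitions by key,
clones by smallest member id).

Query tracing pre-filters the merged repertoire to the query's junction
length and then to the connected component of the compatibility relation
containing the query, adds the query, clusters, and returns the query's
clone. Restricting to the full compatibility component (rather than to
records directly sharing a gene with the query) is what makes the
pre-filter provably equivalent to clustering the whole repertoire — a
directly-matched filter can drop members connected to the query only
through a chain of overlapping ambiguous calls. The equivalence is enforced
by test.

## UCA reconstruction (D-masking)

One germline is built per clone. V and J genes are majority votes over the
members' gene-level calls (tie → lexicographically smallest); gene-level
names resolve to the reference's first allele (`*01` convention). The
member with the highest copy count anchors the coordinates: germline V
covers `[0, v_end)`, germline J covers `[j_start, L)`, and everything
between — N/P additions and the D segment, whose calls are too unreliable
to use — is written as `N`. Germline-side offsets use the AIRR
`v_germline_end` / `j_germline_start` columns when present (supporting 3'/5'
exonuclease-trimmed segments) and default to segment ends otherwise. When
region annotations are missing entirely, the whole junction is masked.
Unmasked UCA positions depend only on the germline reference and the calls,
never on member SHM.

## Lineage trees

Trees are built over the distinct CDR1–FWR4 sequences of a clone plus the
UCA, which participates as an ordinary leaf. Scoring is Fitch small
parsimony with ambiguous symbols as full nucleotide sets — the UCA's `N`
mask therefore never costs a substitution, while real junction differences
between members still count.

Search is exact (full enumeration of the (2n−5)!! unrooted binary
topologies) up to `max_exhaustive = 7` leaves; beyond that, seeded stepwise
addition followed by nearest-neighbour-interchange hill climbing to a local
optimum, deterministic given the seed. When exhaustive, the number of
co-optimal topologies is reported.

Internal sequences are realized by a Fitch backtrace that prefers the
parent's state (minimizing spurious distinct nodes); the root's masked
positions are realized from its child's state, which is cost-free and makes
every node sequence concrete — a prerequisite for exact zero-edge
contraction. The tree is rooted at the UCA, edges oriented away from it,
zero-weight edges contracted (germline identity wins over observed over
inferred; copy counts and compartment/isotype multisets aggregate), after
which every edge weight is ≥ 1 and the edge-weight sum equals the
substitution count of the realized labeling.

## Lineage statistics

Expansion is the sum of `duplicate_count` per compartment ("read copies");
diversification the number of distinct V-region nucleotide sequences.
Germline rows, inferred nodes and the drop-in query itself (a single-cell
sequence, not a repertoire read) are excluded from all counts.
`class_switched` is true when any member carries IgG/IgA/IgE — an
`unknown` isotype is treated as absence of evidence, not as a switch.
Tracking rates report, per subject and reactivity label, the fraction of
queries with ≥ 1 non-query relative anywhere and outside the naive
compartments.

## Synthetic data generator

Each clone draws V/D/J segments from a toy reference (defaults: 4 V of
102 nt, 3 D of 18 nt, 4 J of 45 nt, single allele per gene), applies small
3'/5' exonuclease truncations (0–2 nt) and N additions of 4–10 nt per
junction side — junction lengths land in the realistic 34–50 nt range —
then grows a random branching genealogy: each member mutates a random
earlier member with Poisson(2) point substitutions, at most one of which
falls in the junction per branch (junctions are conserved within clones, as
the clustering model assumes). Compartments advance irreversibly N → A → M
with probability 0.45 per branch; isotypes switch irreversibly IgM →
IgG/IgA/IgE with probability 0.3. True reads carry 5–60 copies; with
probability 0.25 a read spawns a 1-mismatch artifact with 1–4 copies.
Non-productive reads (3%) are standalone junk rearrangements rather than
clone members — frameshifted rearrangements do not clonally expand — so
the productive filter never disconnects a genealogy. Junctions of clones
sharing a (V, J, length) partition are kept ≥ 0.25 normalized distance
apart by rejection, making the planted within/between bimodality real;
`distance_separation_report` verifies it before any recovery claim.

What the generator does *not* emulate: SHM hot/cold spots and transition
bias, indels, allele-level call ambiguity, primer/chimera artifacts beyond
the 1-mismatch error model, and repertoire-scale sequencing depth. Passing
recovery tests therefore demonstrate the pipeline's logic — partitioning,
thresholding, linkage, masking, parsimony — under the model's own
assumptions, not robustness to every artifact of real AIRR-seq data.

## Problem sizes and numerics

Default test and acceptance scales: 30-clone subjects (~120–170 records,
three compartments), 200 random repertoires of ≤ 15 records for the
clustering oracle, 50 random sets of ≤ 6 sequences for parsimony
exactness, 100 bimodal profiles of n = 2000 distances for threshold
behaviour, 50 clones for UCA recovery. These sizes exercise every code
path while keeping a full run in seconds. All aggregation is exact integer
arithmetic; all stochastic components (generator, tree search order) take
explicit seeds, and the end-to-end pipeline is byte-reproducible given
(inputs, config, seed) — run logs contain no timestamps.

## Known limitations

- Hamming-only comparison: a single SHM indel removes a member from its
  clone's metric space.
- Gene-level (not allele-level) call comparison everywhere, mirroring the
  clustering flags the pipeline is built around.
- NNI hill climbing carries no optimality guarantee beyond 7 leaves; the
  returned score is only guaranteed ≤ the stepwise-addition start tree.
- One UCA per clone; per-member germlines (non-"cloned" semantics) are not
  produced.
- No light-chain pairing; heavy-chain-only lineages can conflate cells
  that differ in IgK/L.
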