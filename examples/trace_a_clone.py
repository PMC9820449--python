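"""Trace one characterized IgH sequence through a multi-compartment repertoire.

Simulates a subject with 30 planted B-cell clones across naive (N), atypical
naive (A) and memory (M) compartments, cleans each compartment library,
detects the clonal distance threshold automatically, then drops one clone's
founder sequence into the merged repertoire and extracts its clonotype group.
"""

from iglineage import IgHRecord, SimConfig, make_toy_reference, simulate_repertoire
from iglineage.clonotype import merge_compartments, trace_query
from iglineage.distance import dist_to_nearest, find_threshold
from iglineage.preprocess import preprocess_repertoire, trim_to_cdr1_fwr4

ref = make_toy_reference(seed=4)
reps, truth = simulate_repertoire(SimConfig(seed=4, n_clones=30), ref)
print(f"simulated {sum(len(r) for r in reps)} records in {len(reps)} compartments")

cleaned = [preprocess_repertoire(rep)[0] for rep in reps]
merged = merge_compartments(cleaned)
print(f"after cleaning: {len(merged)} records merged across compartments")

profile = dist_to_nearest(merged)
threshold = find_threshold(profile)
print(f"auto-detected clonal distance threshold: {threshold:.2f}")

# the founder of the first planted clone plays the in vitro characterized query
clones = truth.clones.set_index("clone_id")
clone_id = clones.index[0]
founder = truth.records[(truth.records.clone_id == clone_id)
                        & ~truth.records.is_error_variant].iloc[0]
query = trim_to_cdr1_fwr4(IgHRecord(
    sequence_id="my_antibody",
    sequence=founder.sequence,
    v_call=frozenset({clones.loc[clone_id, "v_allele"]}),
    j_call=frozenset({clones.loc[clone_id, "j_allele"]}),
    junction=founder.junction,
    productive=True,
    cdr1_start=int(clones.loc[clone_id, "cdr1_start"]),
))

group = trace_query(query, merged, threshold)
relatives = group.non_query_members()
compartments = sorted({m.compartment for m in relatives})
print(f"query joined clone {group.clone_id}: {len(relatives)} relatives "
      f"in compartments {compartments}")
# relatives are the query's clonal family — sequences inferred to descend
# from the same V(D)J recombination event, found in the bulk repertoire
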