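import pytest

from iglineage import (
    IgHRecord,
    Repertoire,
    SimConfig,
    make_toy_reference,
    simulate_repertoire,
)
from iglineage.clonotype import merge_compartments
from iglineage.preprocess import preprocess_repertoire


def make_record(sid, junction="TGTGCGAAATGG", v="IGHV1-1*01", j="IGHJ1-1*01", **kw):
    """Minimal valid record whose sequence embeds its junction."""
    seq = kw.pop("sequence", "ACGT" * 5 + junction + "GGCA" * 5)
    defaults = dict(
        sequence_id=sid,
        sequence=seq,
        v_call=frozenset(v.split(",")),
        j_call=frozenset(j.split(",")),
        junction=junction,
        productive=True,
    )
    defaults.update(kw)
    return IgHRecord(**defaults)


@pytest.fixture(scope="session")
def sim_subject():
    """One simulated 30-clone subject plus its preprocessed merged repertoire."""
    ref = make_toy_reference(seed=11)
    config = SimConfig(seed=11, n_clones=30)
    reps, truth = simulate_repertoire(config, ref)
    cleaned = [preprocess_repertoire(r)[0] for r in reps]
    merged = merge_compartments(cleaned)
    return {"ref": ref, "config": config, "reps": reps, "truth": truth, "merged": merged}


def founder_query(truth, clones_ix, clone_id):
    """The clone founder re-packaged as an (untrimmed) drop-in query record."""
    sub = truth.records[truth.records.clone_id == clone_id]
    founder = sub[~sub.is_error_variant].iloc[0]
    return IgHRecord(
        sequence_id=f"query_{clone_id}",
        sequence=founder.sequence,
        v_call=frozenset({clones_ix.loc[clone_id, "v_allele"]}),
        j_call=frozenset({clones_ix.loc[clone_id, "j_allele"]}),
        junction=founder.junction,
        productive=True,
        compartment="query",
        cdr1_start=clones_ix.loc[clone_id, "cdr1_start"],
    )
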