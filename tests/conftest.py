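import pytest

from lncregnet.synthetic_data import (
    SimParams,
    simulate_annotation,
    simulate_cerna,
    simulate_expression,
    simulate_species_sets,
)

SEED = 11


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(seed=SEED)


@pytest.fixture(scope="session")
def small_params():
    return SimParams(
        seed=SEED, n_genes=30, n_lnc_per_class=4, n_filter_decoys=2,
        genome_len=400_000, n_planted_trans_pairs=10, n_mirnas=3,
        n_species=3, n_families=4, n_lnc_per_species=8, n_planted_homologs=4,
    )


@pytest.fixture(scope="session")
def ann_sim(sim_params):
    return simulate_annotation(sim_params)


@pytest.fixture(scope="session")
def expr_sim(ann_sim, sim_params):
    lnc_ids = [
        r.transcript_id
        for r in ann_sim.truth.itertuples(index=False)
        if r.expected_retained or r.category == "lowfpkm_mono"
    ]
    mrna_ids = [g.gene_id for g in ann_sim.genes]
    low = [t for t in lnc_ids if t.startswith("MONO_")]
    return simulate_expression(lnc_ids, mrna_ids, sim_params, low_fpkm_ids=low)


@pytest.fixture(scope="session")
def cerna_sim(sim_params):
    return simulate_cerna(sim_params)


@pytest.fixture(scope="session")
def species_sim(sim_params):
    return simulate_species_sets(sim_params)
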