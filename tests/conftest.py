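import numpy as np
import pandas as pd
import pytest

from gcmemory.params import BurstParams, GCParams, LocalizationParams, SamplingParams
from gcmemory.simulate import sample_repertoire, simulate_truth, write_truth

ONE_TISSUE = LocalizationParams(tissues=("BM",))


@pytest.fixture(scope="session")
def gc_default():
    """Memory 0.014 vs pooled ASC 0.010; total event rate 0.1."""
    return GCParams(death_rate=0.076)


@pytest.fixture(scope="session")
def sim_large(gc_default):
    """Large single-tissue constant-rate simulation (rate inference)."""
    res = simulate_truth(
        gc_default, ONE_TISSUE, BurstParams(), 1, 200_000, 0.0, seed=11,
        founder_dist="fixed", sequences=False,
    )
    res.cells = res.cells.rename(columns={"clone_id": "vdj_key"})
    return res


@pytest.fixture(scope="session")
def sim_multi():
    """Multi-tissue simulation with leakage, naive cells and bursts."""
    gc = GCParams(death_rate=0.076)
    loc = LocalizationParams(tissues=("BM", "Spleen", "Blood"), leak_prob=0.002)
    burst = BurstParams(burst_lineage_prob=0.05, burst_size_mean=20)
    return simulate_truth(gc, loc, burst, 600, 12, 0.25, seed=13)


@pytest.fixture(scope="session")
def records_multi(sim_multi):
    rec = sample_repertoire(
        sim_multi.cells, "d1", SamplingParams(emulsions_per_tissue=2), seed=14
    )
    rec["lineage_id"] = rec["true_lineage_id"]
    return rec


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, sim_multi, records_multi):
    path = tmp_path_factory.mktemp("dataset")
    write_truth(records_multi, str(path), sim_multi.lineages)
    return str(path)


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal cell-record table from compact dict rows."""
    defaults = {
        "donor": "d1",
        "tissue": "BM",
        "emulsion_id": "BM-e1",
        "cell_type": "Memory",
        "isotype": "IGHM",
        "v_gene": "IGHV1-1",
        "j_gene": "IGHJ1",
        "junction_nt": "ACGT" * 10,
        "m": 1,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, cell_id=i, **row)
        r.setdefault("vdj_key", i)
        out.append(r)
    return pd.DataFrame(out)
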