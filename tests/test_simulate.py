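"""Generative-model tests: geometric marginals, localization, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from gcmemory.params import BurstParams, GCParams, LocalizationParams, SamplingParams
from gcmemory.simulate import (
    sample_repertoire,
    simulate_truth,
    theoretical_summary,
    write_truth,
)
from gcmemory.repertoire import read_inputs

ONE = LocalizationParams(tissues=("BM",))


def test_absorbing_death_yields_only_naive_cells():
    gc = GCParams(exit_rates={"Memory": 0.0}, death_rate=1.0)
    res = simulate_truth(gc, ONE, BurstParams(), 50, 5, 0.5, seed=1)
    assert set(res.cells["cell_type"]) <= {"Naive"}
    assert (res.cells["m"] == 0).all()


def test_memory_m_distribution_is_geometric(gc_default, sim_large):
    """With zero dispersion, exit m ~ Geom(Λ): mean (1-Λ)/Λ, GOF at α=0.01."""
    lam = gc_default.total_event_rate
    m = sim_large.cells.loc[sim_large.cells["cell_type"] == "Memory", "m"].to_numpy()
    expected_mean = (1 - lam) / lam
    se = np.sqrt((1 - lam) / lam**2 / m.size)
    assert abs(m.mean() - expected_mean) < 3 * se
    kmax = int(stats.geom.ppf(0.999, lam)) - 1
    obs = np.bincount(np.minimum(m, kmax + 1), minlength=kmax + 2)
    pk = lam * (1 - lam) ** np.arange(kmax + 1)
    _, p = stats.chisquare(obs, m.size * np.append(pk, 1 - pk.sum()))
    assert p > 0.01


def test_type_mixture_constant_in_m(sim_large):
    """Fraction of Memory among exits at fixed m is r_t/Σr, independent of m."""
    cells = sim_large.cells
    expected = 0.014 / 0.024
    for lo, hi in [(1, 5), (10, 20), (25, 40)]:
        sub = cells[(cells["m"] >= lo) & (cells["m"] <= hi)]
        frac = (sub["cell_type"] == "Memory").mean()
        se = np.sqrt(expected * (1 - expected) / len(sub))
        assert abs(frac - expected) < 4 * se


def test_no_leak_means_single_tissue_lineages():
    loc = LocalizationParams(tissues=("BM", "Spleen"), leak_prob=0.0)
    res = simulate_truth(GCParams(death_rate=0.076), loc, BurstParams(), 200, 10, 0.0, seed=2)
    assert (res.cells.groupby("lineage_id")["tissue"].nunique() == 1).all()


def test_leak_dispersal_law():
    """P(lineage seen outside home) = 1-(1-p)^n within binomial error."""
    p = 0.01
    loc = LocalizationParams(tissues=("BM", "Spleen"), leak_prob=p)
    res = simulate_truth(
        GCParams(death_rate=0.076), loc, BurstParams(), 2000, 30, 0.0, seed=3,
        sequences=False,
    )
    lin = res.lineages.merge(
        res.cells.groupby("lineage_id")["tissue"].nunique().rename("n_tis"),
        left_on="lineage_id", right_index=True, how="left",
    ).fillna({"n_tis": 0})
    lin = lin[lin["n_exits"] > 0]
    expected = (1 - (1 - p) ** lin["n_exits"]).mean()
    observed = (lin["n_tis"] > 1).mean()
    se = np.sqrt(expected * (1 - expected) / len(lin))
    assert abs(observed - expected) < 4 * se


def test_identical_seed_identical_output():
    args = (GCParams(death_rate=0.076), ONE, BurstParams(burst_lineage_prob=0.1))
    a = simulate_truth(*args, 100, 8, 0.2, seed=5)
    b = simulate_truth(*args, 100, 8, 0.2, seed=5)
    assert_frame_equal(a.cells, b.cells)
    c = simulate_truth(*args, 100, 8, 0.2, seed=6)
    assert not a.cells.equals(c.cells)


def test_max_cycles_attrition_counted():
    gc = GCParams(exit_rates={"Memory": 0.001}, death_rate=0.001, max_cycles=20)
    res = simulate_truth(gc, ONE, BurstParams(), 100, 20, 0.0, seed=7,
                         founder_dist="fixed", sequences=False)
    assert res.attrition["n_discarded"] > 0
    assert (res.cells["m"] < 20).all()


def test_total_rate_above_one_rejected():
    with pytest.raises(ValueError, match="exceeds 1"):
        GCParams(exit_rates={"Memory": 0.6}, death_rate=0.6)


class TestTheoreticalSummary:
    def test_symmetric_two_type_mixture(self):
        gc = GCParams(exit_rates={"A": 0.02, "B": 0.02}, death_rate=0.06)
        s = theoretical_summary(gc)
        assert s["lambda_total"] == pytest.approx(0.1)
        assert s["types"]["A"]["p_type"] == pytest.approx(0.5)
        assert s["types"]["A"]["mean_m"] == pytest.approx(9.0, abs=1e-6)

    def test_single_exit_type_probability_one(self):
        gc = GCParams(exit_rates={"Memory": 0.05}, death_rate=0.05)
        assert theoretical_summary(gc)["types"]["Memory"]["p_type"] == 1.0

    def test_dispersion_refused(self):
        gc = GCParams(death_rate=0.076, lineage_rate_dispersion=0.5)
        with pytest.raises(ValueError, match="dispersion"):
            theoretical_summary(gc)

    def test_suppressed_low_m_exit_probability_vs_simulation(self):
        """Closed form P(exit, m<s) = (fΣr/Λ_low)(1-(1-Λ_low)^s)."""
        gc = GCParams(
            exit_rates={"Memory": 0.014, "ASC-3": 0.01},
            death_rate=0.076,
            suppression_factor=0.5,
            m_stab=10,
        )
        s = theoretical_summary(gc)
        f, sr, d = 0.5, 0.024, 0.076
        lam_low = f * sr + d
        closed = (sr * f / lam_low) * (1 - (1 - lam_low) ** 10)
        assert s["p_exit_low_m"] == pytest.approx(closed)
        res = simulate_truth(gc, ONE, BurstParams(), 1, 100_000, 0.0, seed=8,
                             founder_dist="fixed", sequences=False)
        n_found = res.attrition["n_founders"]
        sim_frac = (res.cells["m"] < 10).sum() / n_found
        se = np.sqrt(closed * (1 - closed) / n_found)
        assert abs(sim_frac - closed) < 4 * se
        # fraction of exits above threshold agrees too
        sim_mature = (res.cells["m"] >= 10).mean()
        assert sim_mature == pytest.approx(s["frac_mature_exits"], abs=0.01)


def test_poisson_mutation_path_runs():
    gc = GCParams(death_rate=0.076, mutation_dist="poisson", mutations_per_cycle=1.5)
    res = simulate_truth(gc, ONE, BurstParams(), 50, 10, 0.0, seed=9, sequences=False)
    assert len(res.cells) > 0
    s = theoretical_summary(GCParams(death_rate=0.076, mutation_dist="poisson",
                                     mutations_per_cycle=1.5))
    assert s["types"]["Memory"]["mean_m"] == pytest.approx(1.5 * 9.0, rel=0.01)


class TestSampleRepertoire:
    def test_full_capture_single_emulsion_is_identity(self, sim_multi):
        sp = SamplingParams(emulsions_per_tissue=1, capture_prob=1.0)
        rec = sample_repertoire(sim_multi.cells, "d1", sp, seed=1)
        assert len(rec) == len(sim_multi.cells)
        assert rec["emulsion_id"].nunique() == sim_multi.cells["tissue"].nunique()

    def test_zero_capture_warns_and_is_empty(self, sim_multi):
        with pytest.warns(UserWarning):
            rec = sample_repertoire(
                sim_multi.cells, "d1", SamplingParams(capture_prob=0.0), seed=1
            )
        assert len(rec) == 0

    def test_binomial_thinning(self, sim_multi):
        n = len(sim_multi.cells)
        rec = sample_repertoire(
            sim_multi.cells, "d1", SamplingParams(capture_prob=0.5), seed=2
        )
        assert abs(len(rec) - 0.5 * n) < 3 * np.sqrt(n * 0.25)


class TestWriteTruth:
    def test_roundtrip(self, dataset_dir, records_multi):
        back = read_inputs(f"{dataset_dir}/airr.tsv", f"{dataset_dir}/meta.tsv")
        assert len(back) == len(records_multi)
        j = back.merge(records_multi, on="cell_id", suffixes=("", "_t"))
        assert (j["m"] == j["m_t"]).all()
        assert (j["junction_nt"] == j["junction_nt_t"]).all()
        assert (j["tissue"] == j["tissue_t"]).all()
        # donor-scoped sequence key reproduces the true clone partition
        assert j.groupby("vdj_key")["vdj_key_t"].nunique().max() == 1
        assert j.groupby("vdj_key_t")["vdj_key"].nunique().max() == 1

    def test_schema_columns(self, dataset_dir):
        airr = pd.read_csv(f"{dataset_dir}/airr.tsv", sep="\t", nrows=1)
        assert list(airr.columns) == [
            "sequence_id", "cell_id", "v_call", "j_call", "junction",
            "sequence", "v_mutation_count",
        ]
        meta = pd.read_csv(f"{dataset_dir}/meta.tsv", sep="\t", nrows=1)
        assert list(meta.columns) == [
            "cell_id", "donor", "tissue", "emulsion_id", "cell_type", "isotype",
        ]

    def test_sidecar_lineage_count(self, dataset_dir, sim_multi):
        side = pd.read_csv(f"{dataset_dir}/truth_lineages.tsv", sep="\t")
        assert len(side) == len(sim_multi.lineages) == 600

    def test_requires_sequences(self, tmp_path):
        gc = GCParams(death_rate=0.076)
        res = simulate_truth(gc, ONE, BurstParams(), 10, 5, 0.0, seed=1,
                             sequences=False)
        rec = sample_repertoire(res.cells, "d1", SamplingParams(), seed=2)
        with pytest.raises(ValueError, match="sequences"):
            write_truth(rec, str(tmp_path))
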