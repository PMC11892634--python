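"""Exit-hazard estimation, plateau ratios, mixtures, composition nulls."""

import numpy as np
import pandas as pd
import pytest

from gcmemory import gc_model as gm
from gcmemory.params import BurstParams, GCParams, LocalizationParams
from gcmemory.simulate import simulate_truth

from conftest import make_records

ONE = LocalizationParams(tissues=("BM",))


def test_single_type_all_m_one_hazard_is_one():
    rec = make_records([{"m": 1, "vdj_key": i} for i in range(20)])
    hz = gm.exit_hazard(gm.differentiated_members(rec), min_bin_cells=10)
    c = hz["Memory"]
    assert c.lambda_hat[c.m == 1][0] == 1.0


def test_hazard_matches_closed_form_over_all_bins(gc_default, sim_large):
    """Oracle equivalence: lambda_hat_t(m) = r_t Λ/Σr within binomial error."""
    members = gm.differentiated_members(sim_large.cells, min_m=1)
    hz = gm.exit_hazard(members, m_max=35)
    lam, sr = gc_default.total_event_rate, gc_default.total_exit_rate
    for t, h in hz.items():
        expected = gc_default.exit_rates[t] * lam / sr
        sel = ~h.masked
        z = (h.lambda_hat[sel] - expected) / h.se[sel]
        assert np.abs(z).max() < 4.5
        assert np.abs(z.mean()) < 0.5


def test_plateau_ratio_recovery(sim_large):
    members = gm.differentiated_members(sim_large.cells, min_m=1, pool_asc=True)
    pl = gm.plateau_rates(gm.exit_hazard(members), m_stab=10)
    assert pl.ratio("Memory", "ASC") == pytest.approx(1.4, abs=0.05)
    assert pl.ratio("ASC", "Memory") == pytest.approx(1 / 1.4, abs=0.03)
    assert pl.ratio("Memory", "Memory") == 1.0


def test_ratio_invariant_to_death_rate_and_suppression():
    """The Λ/Σr factor cancels in ratios: death and suppression drop out."""
    ratios = []
    for death, supp in [(0.026, 1.0), (0.126, 1.0), (0.076, 0.5)]:
        gc = GCParams(death_rate=death, suppression_factor=supp, m_stab=10)
        res = simulate_truth(gc, ONE, BurstParams(), 1, 150_000, 0.0, seed=41,
                             founder_dist="fixed", sequences=False)
        cells = res.cells.rename(columns={"clone_id": "vdj_key"})
        members = gm.differentiated_members(cells, min_m=1, pool_asc=True)
        pl = gm.plateau_rates(gm.exit_hazard(members), m_stab=10)
        ratios.append(pl.ratio("Memory", "ASC"))
    assert np.allclose(ratios, 1.4, atol=0.06)


def test_scaled_hazard_plateau_averages_to_one(sim_large):
    members = gm.differentiated_members(sim_large.cells, min_m=1)
    hz = gm.exit_hazard(members, m_max=30)
    pl = gm.plateau_rates(hz, m_stab=10)
    curves, spread = gm.scaled_hazard(hz, pl)
    for t, c in curves.items():
        sel = (c["m"] >= 10) & ~c["masked"]
        w = hz[t].at_risk[sel.to_numpy()]
        avg = np.average(c.loc[sel, "scaled"], weights=w)
        assert avg == pytest.approx(1.0, abs=1e-9)
    # rare ASC subtypes are noisy at this size; tight spread bounds are
    # exercised by the large suppression benchmark instead
    assert (spread.loc[spread["m"] <= 15, "spread"] < 0.8).all()


def test_zero_plateau_rejected():
    rec = make_records([{"m": 1, "vdj_key": i} for i in range(20)])
    hz = gm.exit_hazard(gm.differentiated_members(rec), min_bin_cells=1)
    pl = gm.plateau_rates(hz, m_stab=1)
    pl.rates["Memory"] = 0.0
    with pytest.raises(ValueError, match="zero plateau"):
        gm.scaled_hazard(hz, pl)


def test_no_plateau_bins_is_an_error():
    rec = make_records([{"m": 1, "vdj_key": i} for i in range(20)])
    hz = gm.exit_hazard(gm.differentiated_members(rec))
    with pytest.raises(ValueError, match="no unmasked"):
        gm.plateau_rates(hz, m_stab=10)


class TestTypeMixture:
    def test_equal_plateaus_give_half_half_model(self):
        pl = gm.PlateauRates(
            rates={"A": 0.02, "B": 0.02}, ratios={}, m_stab=10
        )
        mix = gm.model_mixture(pl, np.arange(1, 20))
        assert np.allclose(mix.probs, 0.5)

    def test_window_one_is_raw_frequencies(self):
        rec = make_records(
            [{"m": 1, "cell_type": "Memory", "vdj_key": i} for i in range(3)]
            + [{"m": 1, "cell_type": "ASC-1", "vdj_key": 10 + i} for i in range(1)]
        )
        mix = gm.type_mixture(gm.differentiated_members(rec), smoothing_window=1)
        row = mix.probs[mix.m == 1][0]
        assert row[mix.types.index("Memory")] == pytest.approx(0.75)

    def test_even_window_rejected(self):
        rec = make_records([{"m": 1}])
        with pytest.raises(ValueError, match="odd"):
            gm.type_mixture(gm.differentiated_members(rec), smoothing_window=2)

    def test_empirical_matches_model_under_constant_rates(self, gc_default, sim_large):
        members = gm.differentiated_members(sim_large.cells, min_m=1)
        mix = gm.type_mixture(members, smoothing_window=3)
        pl = gm.plateau_rates(gm.exit_hazard(members), m_stab=10)
        model = gm.model_mixture(pl, mix.m, mix.types)
        sel = mix.m <= 30
        n_at = np.array([(members["m"] == m).sum() for m in mix.m[sel]])
        for k in range(len(mix.types)):
            resid = mix.probs[sel, k] - model.probs[sel, k]
            se = np.sqrt(model.probs[sel, k] * (1 - model.probs[sel, k]) / n_at)
            # smoothing correlates neighbors; allow a generous multiple
            assert np.nanmax(np.abs(resid) / se) < 6


class TestCompositionNull:
    def test_contains_probability_closed_form(self):
        """p_t = 0.5 everywhere, lineage of 3: P(contains) = 1 - 0.5^3."""
        mix = gm.TypeMixture(
            types=["A", "B"],
            m=np.arange(1, 10),
            probs=np.full((9, 2), 0.5),
            counts=np.zeros((9, 2)),
            smoothing_window=1,
        )
        rec = make_records(
            [{"m": 2, "cell_type": "A", "vdj_key": i} for i in range(3)]
        )
        rec["lineage_id"] = 0
        null = gm.lineage_composition_null(rec, mix, min_unique=2)
        assert null.per_lineage["p_contains_A"][0] == pytest.approx(0.875)
        assert null.per_lineage["exp_A"][0] == pytest.approx(1.5)

    def test_size_one_lineages_reduce_to_marginals(self):
        rng = np.random.default_rng(3)
        rows = [
            {"m": 1, "cell_type": "A" if rng.random() < 0.7 else "B", "vdj_key": i}
            for i in range(500)
        ]
        rec = make_records(rows)
        rec["lineage_id"] = np.arange(500)
        mix = gm.type_mixture(rec.rename(columns={}), smoothing_window=1)
        null = gm.lineage_composition_null(rec, mix, min_unique=1)
        z = gm.composition_zscores(null)
        # expected fraction equals the marginal frequency exactly
        tot = null.per_lineage[["exp_A", "obs_A"]].sum()
        assert tot["exp_A"] == pytest.approx(tot["obs_A"])
        assert np.allclose(z["z"].abs(), 0.0, atol=1e-9)

    def test_independence_within_three_se(self):
        gc = GCParams(death_rate=0.076)
        res = simulate_truth(gc, ONE, BurstParams(), 2000, 15, 0.0, seed=43,
                             sequences=False)
        cells = res.cells.rename(columns={"clone_id": "vdj_key"})
        members = gm.differentiated_members(cells, min_m=1, unit="cell")
        mix = gm.type_mixture(members, smoothing_window=3)
        null = gm.lineage_composition_null(members, mix, min_unique=2)
        z = gm.composition_zscores(null)
        assert z["z"].abs().max() < 3

    def test_burst_lineages_show_asc3_excess(self):
        gc = GCParams(death_rate=0.076)
        burst = BurstParams(burst_lineage_prob=0.05, burst_size_mean=15)
        res = simulate_truth(gc, ONE, burst, 2000, 15, 0.0, seed=44,
                             sequences=False)
        cells = res.cells.rename(columns={"clone_id": "vdj_key"})
        members = gm.differentiated_members(cells, min_m=1, unit="cell")
        mix = gm.type_mixture(members, smoothing_window=3)
        null = gm.lineage_composition_null(members, mix, min_unique=2)
        z_large = gm.composition_zscores(null, min_size=10)
        z_asc3 = z_large.set_index("cell_type")["z"]
        assert z_asc3["ASC-3"] > 3
        assert z_asc3.drop("ASC-3").max() < 3

    def test_size_bin_filters_applied(self, sim_large):
        members = gm.differentiated_members(
            sim_large.cells, min_m=1, unit="cell"
        ).head(3000)
        members = members.assign(
            lineage_id=np.arange(len(members)) // 3
        )
        mix = gm.type_mixture(members, smoothing_window=3)
        null = gm.lineage_composition_null(
            members, mix, min_unique=2, min_cells=6, min_lineages=10
        )
        assert (null.by_size["n_cells"] >= 6).all()
        assert (null.by_size["n_lineages"] >= 10).all()


class TestFractionMature:
    def test_all_unmutated_is_zero(self):
        rec = make_records([{"m": 0, "vdj_key": i} for i in range(5)])
        assert gm.fraction_mature_exits(
            gm.differentiated_members(rec, min_m=0), 10
        ) == 0.0

    def test_all_mature_is_one(self):
        rec = make_records([{"m": 15, "vdj_key": i} for i in range(5)])
        assert gm.fraction_mature_exits(
            gm.differentiated_members(rec, min_m=0), 10
        ) == 1.0
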