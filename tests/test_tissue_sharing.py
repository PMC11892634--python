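"""Privacy, discovery curves, x_c fitting, clone sizes, sharing estimates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gcmemory import tissue_sharing as tsh
from gcmemory.params import BurstParams, GCParams, LocalizationParams, SamplingParams
from gcmemory.simulate import sample_repertoire, simulate_truth

from conftest import make_records


class TestPrivacy:
    def test_no_leak_fully_private(self, records_multi):
        # remove cross-tissue bursts so colocalization is absolute
        res = simulate_truth(
            GCParams(death_rate=0.076),
            LocalizationParams(tissues=("BM", "Spleen"), leak_prob=0.0),
            BurstParams(), 300, 10, 0.0, seed=51, sequences=False,
        )
        rec = res.cells.rename(columns={"clone_id": "vdj_key"})
        pf = tsh.privacy_fractions(rec, n_perm=20, seed=52)
        assert (pf["fraction_private"] == 1.0).all()
        assert (pf["expected_private"] < 1.0).all()

    def test_shuffled_labels_match_expectation(self):
        rng = np.random.default_rng(53)
        rec = make_records(
            [
                {"tissue": rng.choice(["BM", "Spleen"]), "vdj_key": i}
                for i in range(600)
            ]
        )
        rec["lineage_id"] = rng.integers(0, 150, len(rec))
        pf = tsh.privacy_fractions(rec, n_perm=50, seed=54)
        assert np.allclose(
            pf["fraction_private"], pf["expected_private"], atol=0.1
        )

    def test_all_lineages_everywhere_zero_privacy(self):
        rows = []
        for lid in range(10):
            for t in ("BM", "Spleen"):
                rows.append({"tissue": t, "vdj_key": len(rows)})
        rec = make_records(rows)
        rec["lineage_id"] = np.repeat(np.arange(10), 2)
        pf = tsh.privacy_fractions(rec, n_perm=5, seed=1)
        assert (pf["fraction_private"] == 0.0).all()

    def test_single_tissue_rejected(self):
        rec = make_records([{"vdj_key": 0}])
        rec["lineage_id"] = 0
        with pytest.raises(ValueError, match="two tissues"):
            tsh.privacy_fractions(rec)

    def test_permutation_expectation_matches_enumeration(self):
        """Two equal tissues, lineage sizes {2,1,1}: brute-force over the
        4!/(2!2!) label assignments gives the exact well-mixed value."""
        rec = make_records([{"vdj_key": i} for i in range(4)])
        rec["lineage_id"] = [0, 0, 1, 2]
        labels = ["A", "A", "B", "B"]
        vals = {"A": [], "B": []}
        for perm in set(itertools.permutations(labels)):
            df = rec.assign(tissue=list(perm))
            ntis = df.groupby("lineage_id")["tissue"].nunique()
            for t in ("A", "B"):
                lins = df.loc[df["tissue"] == t, "lineage_id"].unique()
                vals[t].append((ntis.loc[lins] == 1).mean())
        exact = {t: np.mean(v) for t, v in vals.items()}
        rec["tissue"] = labels
        pf = tsh.privacy_fractions(rec, n_perm=4000, seed=55).set_index("tissue")
        for t in ("A", "B"):
            assert pf.loc[t, "expected_private"] == pytest.approx(exact[t], abs=0.03)


class TestDiscovery:
    def test_x_sums_to_one_and_spanning_lineage_found(self, records_multi):
        emu = records_multi.groupby("emulsion_id")["vdj_key"].nunique()
        n = int(emu.min() * 0.8)
        pts = tsh.discovery_curve(records_multi, "Spleen", "Blood", n, seed=1)
        assert pts["x"].sum() == pytest.approx(1.0)
        assert ((pts["x"] > 0) & (pts["x"] <= 1)).all()

    def test_absent_ascertainment_tissue_rejected(self, records_multi):
        with pytest.raises(ValueError, match="ascertainment"):
            tsh.discovery_curve(records_multi, "Gut", "Blood", 10, seed=1)


def _bernoulli_points(seed, n=200, xc=0.01):
    rng = np.random.default_rng(seed)
    x = np.clip(rng.lognormal(-6.5, 1.0, n), 1e-6, 1.0)
    found = rng.random(n) < -np.expm1(-x / xc)
    return pd.DataFrame({"x": x, "found": found})


class TestFitXc:
    def test_matches_bruteforce_grid(self):
        """MLE agrees with a 10^4-point likelihood grid to 4 significant figures."""
        from gcmemory.validation import xc_bruteforce_check

        out = xc_bruteforce_check(seed=61)
        assert out["rel_diff"] < 5e-4

    def test_half_discovery_at_xc_ln2(self):
        fit = tsh.fit_xc(_bernoulli_points(62, n=5000))
        assert -np.expm1(-(fit.x_c * np.log(2)) / fit.x_c) == pytest.approx(0.5)
        assert fit.ci[0] < fit.x_c < fit.ci[1]

    def test_scale_equivariance(self):
        pts = _bernoulli_points(63)
        fit1 = tsh.fit_xc(pts)
        fit2 = tsh.fit_xc(pts.assign(x=2 * pts["x"]))
        assert fit2.x_c == pytest.approx(2 * fit1.x_c, rel=1e-6)

    def test_recovery_from_bernoulli_sampling(self):
        fit = tsh.fit_xc(_bernoulli_points(64, n=5000, xc=0.01))
        assert fit.x_c == pytest.approx(0.01, rel=0.15)

    def test_degenerate_outcomes_rejected(self):
        pts = _bernoulli_points(65)
        with pytest.raises(ValueError, match="identifiable"):
            tsh.fit_xc(pts.assign(found=True))
        with pytest.raises(ValueError, match="10"):
            tsh.fit_xc(pts.head(5))


class TestCloneSizes:
    def test_all_singletons(self):
        rec = make_records([{"vdj_key": i} for i in range(10)])
        hist, expanded = tsh.clone_size_distribution(rec)
        assert set(hist["clone_size"]) == {1}
        assert expanded == 0.0

    def test_planted_expansion_fraction(self):
        """1% of VDJs duplicated: the expanded fraction reads ~0.01."""
        rows = [{"vdj_key": i} for i in range(1000)]
        rows += [{"vdj_key": i} for i in range(10)]  # 10 of 1000 expanded
        rec = make_records(rows)
        rec["cell_id"] = np.arange(len(rec))
        _, expanded = tsh.clone_size_distribution(rec)
        assert expanded == pytest.approx(0.01, abs=0.001)

    def test_burst_sim_asc3_heavy_tail(self, records_multi):
        hist, _ = tsh.clone_size_distribution(records_multi)
        max_by_type = hist.groupby("cell_type")["clone_size"].max()
        assert max_by_type["ASC-3"] > max_by_type.drop("ASC-3").max()


class TestSharing:
    def test_disjoint_tissues_share_nothing(self):
        res = simulate_truth(
            GCParams(death_rate=0.076),
            LocalizationParams(tissues=("BM", "Spleen"), leak_prob=0.0),
            BurstParams(), 400, 10, 0.0, seed=71, sequences=False,
        )
        rec = sample_repertoire(res.cells, "d1",
                                SamplingParams(emulsions_per_tissue=2), seed=72)
        n = int(rec.groupby("emulsion_id")["vdj_key"].nunique().min() * 0.8)
        est = tsh.sharing_probability(rec, ("BM",), "Spleen", n, 10, seed=73)
        assert est.raw == 0.0

    def test_target_in_source_rejected(self, records_multi):
        with pytest.raises(ValueError, match="source_set"):
            tsh.sharing_probability(records_multi, ("BM",), "BM", 10, 5, 1)

    def test_sharing_rises_with_source_set_size(self):
        """Multi-tissue burst clones: conditioning on two tissues implies
        near-certain presence in a third."""
        loc = LocalizationParams(tissues=("BM", "Spleen", "Blood"), leak_prob=0.001)
        burst = BurstParams(burst_lineage_prob=0.08, burst_size_mean=40)
        res = simulate_truth(GCParams(death_rate=0.076), loc, burst,
                             2000, 12, 0.0, seed=74, sequences=False)
        rec = sample_repertoire(res.cells, "d1",
                                SamplingParams(emulsions_per_tissue=2), seed=75)
        n = int(rec.groupby("emulsion_id")["vdj_key"].nunique().min() * 0.8)
        one = tsh.sharing_probability(rec, ("BM",), "Blood", n, 20, seed=76)
        two = tsh.sharing_probability(rec, ("BM", "Spleen"), "Blood", n, 20, seed=77)
        assert two.raw > one.raw
        assert two.raw > 0.5

    def test_replicate_normalization_is_unity(self):
        from gcmemory.validation import normalization_benchmark

        out = normalization_benchmark(seed=78, n_lineages=1500)
        assert out["replicate_normalized"] == pytest.approx(1.0, abs=0.1)
        assert out["capture_invariance_absdiff"] < 0.15

    def test_missing_replicates_rejected(self, records_multi):
        single = records_multi[records_multi["emulsion_id"] == "BM-e1"]
        est = tsh.SharingEstimate(("BM",), "Spleen", 0.5, 0.0, 3, 50)
        with pytest.raises(ValueError, match="emulsions"):
            tsh.normalize_sharing(est, single, seed=1)
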