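"""Parameter-recovery benchmarks run end-to-end through the package.

Each benchmark simulates a ground-truthed repertoire under known study
conditions, runs the corresponding inference path, and reports how well the
generative parameters are recovered.  These are the quantitative checks
behind the test suite and the acceptance script; problem sizes are chosen
so each benchmark has comfortable statistical resolution at interactive
runtimes (documented in the methods note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import gc_model as gm
from . import lineage_stats as ls
from . import tissue_sharing as tsh
from .params import BurstParams, GCParams, LocalizationParams, SamplingParams
from .simulate import sample_repertoire, simulate_truth

__all__ = [
    "rate_ratio_benchmark",
    "geometric_gof_benchmark",
    "scaled_hazard_benchmark",
    "xc_recovery_benchmark",
    "xc_bruteforce_check",
    "permutation_calibration_benchmark",
    "composition_benchmark",
    "normalization_benchmark",
    "simpson_benchmark",
    "mature_exit_benchmark",
]

_ONE_TISSUE = LocalizationParams(tissues=("BM",))


def _seeds(seed: int, n: int, key: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def _truth_vdjs(res) -> pd.DataFrame:
    return res.cells.rename(columns={"clone_id": "vdj_key"})


def rate_ratio_benchmark(seed: int, n_founders: int = 500_000) -> dict:
    """Recover the Memory/ASC long-term rate ratio (true value 1.4).

    Simulates at the default exit rates (Memory 0.014, pooled ASC 0.010,
    total event rate 0.1) and estimates plateau rates from the hypermutation
    histogram with ASC subtypes pooled.
    """
    gc = GCParams(death_rate=0.076)
    res = simulate_truth(
        gc, _ONE_TISSUE, BurstParams(), 1, n_founders, 0.0, seed,
        founder_dist="fixed", sequences=False,
    )
    members = gm.differentiated_members(_truth_vdjs(res), min_m=1, pool_asc=True)
    plateaus = gm.plateau_rates(gm.exit_hazard(members), m_stab=10)
    return {
        "ratio": plateaus.ratio("Memory", "ASC"),
        "true_ratio": 0.014 / 0.010,
        "n_exits": int(len(members.drop_duplicates("vdj_key"))),
    }


def geometric_gof_benchmark(
    seed: int, n_runs: int = 20, n_founders: int = 100_000, alpha: float = 0.01
) -> dict:
    """Chi-square goodness of fit of per-type m distributions to Geom(Λ).

    Under the constant-rate model every exit type's hypermutation count is
    geometric with the total per-cycle event rate Λ = 0.1.  One chi-square
    test per (run, type) with the known Λ; reports the non-rejection rate.
    """
    gc = GCParams(death_rate=0.076)
    lam = gc.total_event_rate
    n_pass = n_tests = 0
    for s in _seeds(seed, n_runs, key=2):
        res = simulate_truth(
            gc, _ONE_TISSUE, BurstParams(), 1, n_founders, 0.0, s,
            founder_dist="fixed", sequences=False,
        )
        cells = res.cells
        for t in gc.types:
            m = cells.loc[cells["cell_type"] == t, "m"].to_numpy()
            if m.size < 200:
                continue
            # truncate where expected per-bin counts stay >= 5 so the
            # chi-square sampling distribution is valid for rare types
            kmax = int(np.log(5.0 / (m.size * lam)) / np.log1p(-lam))
            kmax = max(kmax, 5)
            obs = np.bincount(np.minimum(m, kmax + 1), minlength=kmax + 2)
            pk = lam * (1 - lam) ** np.arange(kmax + 1)
            probs = np.append(pk, 1 - pk.sum())
            _, p = stats.chisquare(obs, m.size * probs)
            n_tests += 1
            n_pass += p > alpha
    return {"pass_rate": n_pass / n_tests, "n_tests": n_tests, "alpha": alpha}


def scaled_hazard_benchmark(seed: int, n_founders: int = 1_000_000) -> dict:
    """Constancy and equal-suppression structure of scaled exit hazards.

    Run 1 (suppression 1): scaled hazards should be 1 for m in [10, 30].
    Run 2 (suppression 0.5, death 0 so the exits-only hazard is exactly the
    per-cycle exit rate): scaled hazards of all types should sit at 0.5
    below m_stab, with small cross-type spread.
    """
    rates = {"Memory": 0.0583, "ASC": 0.0417}
    out: dict = {}
    s1, s2 = _seeds(seed, 2, key=3)

    gc1 = GCParams(exit_rates=rates, death_rate=0.0)
    res = simulate_truth(
        gc1, _ONE_TISSUE, BurstParams(), 1, n_founders, 0.0, s1,
        founder_dist="fixed", sequences=False,
    )
    members = gm.differentiated_members(_truth_vdjs(res), min_m=1)
    hz = gm.exit_hazard(members, m_max=40)
    curves, _ = gm.scaled_hazard(hz, gm.plateau_rates(hz, 10))
    devs = []
    for c in curves.values():
        sel = (c["m"] >= 10) & (c["m"] <= 30) & ~c["masked"]
        devs.append(np.abs(c.loc[sel, "scaled"] - 1.0).max())
    out["plateau_max_abs_dev"] = float(max(devs))
    out["n_exits"] = int(len(members.drop_duplicates("vdj_key")))

    gc2 = GCParams(
        exit_rates=rates, death_rate=0.0, suppression_factor=0.5, m_stab=10
    )
    res2 = simulate_truth(
        gc2, _ONE_TISSUE, BurstParams(), 1, n_founders, 0.0, s2,
        founder_dist="fixed", sequences=False,
    )
    members2 = gm.differentiated_members(_truth_vdjs(res2), min_m=0)
    hz2 = gm.exit_hazard(members2, m_max=40)
    curves2, spread2 = gm.scaled_hazard(hz2, gm.plateau_rates(hz2, 10))
    low_devs, low_vals = [], []
    for c in curves2.values():
        sel = (c["m"] < 10) & ~c["masked"]
        low_devs.append(np.abs(c.loc[sel, "scaled"] - 0.5).max())
        low_vals.extend(c.loc[sel, "scaled"].tolist())
    low_spread = spread2.loc[spread2["m"] < 10, "spread"]
    out["suppressed_low_m_mean"] = float(np.mean(low_vals))
    out["suppressed_max_abs_dev"] = float(max(low_devs))
    out["suppressed_spread_max"] = float(low_spread.max())
    return out


def xc_recovery_benchmark(
    seed: int,
    leaks: tuple[float, ...] = (0.004, 0.008, 0.016),
    n_lineages: int = 12_000,
) -> dict:
    """Recover the dispersal critical size x_c across a leak-probability grid.

    One-directional leakage (spleen -> blood) keeps the ascertainment tissue
    free of reverse-leak contamination, so the generative critical size is
    exactly x_c = 1 / (leak * N_A * ret_B), with N_A the ascertainment
    tissue's unique VDJs and ret_B the fraction of target-tissue unique VDJs
    retained by downsampling.
    """
    fits = {}
    for leak, s in zip(leaks, _seeds(seed, len(leaks), key=4)):
        gc = GCParams(death_rate=0.076)
        loc = LocalizationParams(
            tissues=("Spleen", "Blood"),
            home_weights=(0.5, 0.5),
            leak_prob={("Spleen", "Blood"): leak},
        )
        res = simulate_truth(
            gc, loc, BurstParams(), n_lineages, 40, 0.0, s, sequences=False
        )
        rec = sample_repertoire(
            res.cells, "d1", SamplingParams(emulsions_per_tissue=2), s + 1
        )
        rec["lineage_id"] = rec["true_lineage_id"]
        emu = rec.groupby("emulsion_id")["vdj_key"].nunique()
        n_unique = int(emu.min() * 0.8)
        pts = tsh.discovery_curve(rec, "Spleen", "Blood", n_unique, s + 2)
        fit = tsh.fit_xc(pts)
        n_a = rec.loc[rec["tissue"] == "Spleen", "vdj_key"].nunique()
        ret_b = 2 * n_unique / rec.loc[rec["tissue"] == "Blood", "vdj_key"].nunique()
        true_xc = 1.0 / (leak * n_a * ret_b)
        fits[leak] = {
            "x_c": fit.x_c,
            "true_x_c": true_xc,
            "rel_error": fit.x_c / true_xc - 1.0,
            "ci": fit.ci,
            "n_points": fit.n_points,
        }
    return {
        "max_abs_rel_error": float(
            max(abs(v["rel_error"]) for v in fits.values())
        ),
        "fits": fits,
    }


def xc_bruteforce_check(seed: int, n_points: int = 200) -> dict:
    """MLE vs brute-force likelihood grid on a small synthetic point set."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(-6.5, 1.0, n_points)
    x = np.clip(x, 1e-6, 1.0)
    true_xc = 0.01
    found = rng.random(n_points) < -np.expm1(-x / true_xc)
    if not (found.any() and not found.all()):  # pragma: no cover
        raise RuntimeError("degenerate draw")
    pts = pd.DataFrame({"x": x, "found": found})
    fit = tsh.fit_xc(pts)
    grid = np.geomspace(true_xc / 100, true_xc * 100, 10_000)
    with np.errstate(divide="ignore"):
        ll = np.array(
            [
                np.log(-np.expm1(-x[found] / g)).sum() - (x[~found] / g).sum()
                for g in grid
            ]
        )
    brute = float(grid[np.argmax(ll)])
    return {
        "mle": fit.x_c,
        "brute_force": brute,
        "rel_diff": abs(fit.x_c / brute - 1.0),
        "n_points": n_points,
    }


def _calibration_dataset(s: int, n_lineages: int = 600):
    gc = GCParams(death_rate=0.076)
    loc = LocalizationParams(tissues=("BM", "Spleen", "Blood"), leak_prob=0.01)
    res = simulate_truth(
        gc, loc, BurstParams(), n_lineages, 60, 0.0, s, sequences=False
    )
    cells = _truth_vdjs(res)
    # cell-type labels are drawn independently within lineages, the cleanest
    # label-independent null; ASC subtypes pooled for item counts
    cells.loc[cells["cell_type"].str.startswith("ASC"), "cell_type"] = "ASC"
    return cells


def permutation_calibration_benchmark(
    seed: int, n_runs: int = 20, n_perm: int = 100
) -> dict:
    """Coverage of the within-lineage permutation band, and its power.

    Null runs: cell-type labels are assigned independently of m within
    lineages by the constant-rate model, so the measured CDF should lie
    inside the band at >= 90% of grid points.  Planted runs: the 'BM' label
    is re-assigned preferentially to each lineage's most-hypermutated
    members; the band should be exceeded.
    """
    coverage_ok = detected = 0
    coverages = []
    for s in _seeds(seed, n_runs, key=5):
        cells = _calibration_dataset(s)
        rel = ls.relative_levels(cells, "cell_type", 5)
        bands = ls.permutation_band(rel, n_perm, s + 1)
        diff = ls.cdf_difference(rel, bands["Memory"], "Memory")
        cov = float(diff["inside"].mean())
        coverages.append(cov)
        coverage_ok += cov >= 0.9

        # planted label-m association: BM goes to the top of each lineage
        rng = np.random.default_rng(s + 2)
        planted = rel.copy()
        high = planted["rel"].to_numpy() >= 0.7
        p_bm = np.where(high, 0.6, 0.05)
        planted["label"] = np.where(
            rng.random(len(planted)) < p_bm, "BM", "Other"
        )
        bands_p = ls.permutation_band(planted, n_perm, s + 3)
        diff_p = ls.cdf_difference(planted, bands_p["BM"], "BM")
        detected += not bool(diff_p["inside"].all())
    return {
        "coverage_rate": coverage_ok / n_runs,
        "mean_coverage": float(np.mean(coverages)),
        "detection_rate": detected / n_runs,
        "n_runs": n_runs,
    }


def composition_benchmark(seed: int, n_lineages: int = 3000) -> dict:
    """Lineage type content vs the independence null, with and without bursts.

    Without bursts every type's observed count should match the null within
    3 SE; with ASC-3 bursts enabled, ASC-3 — and only ASC-3 — should show a
    systematic excess among large lineages.
    """
    s1, s2 = _seeds(seed, 2, key=6)
    gc = GCParams(death_rate=0.076)

    def run(burst: BurstParams, s: int):
        res = simulate_truth(
            gc, _ONE_TISSUE, burst, n_lineages, 15, 0.0, s, sequences=False
        )
        cells = gm.differentiated_members(_truth_vdjs(res), min_m=1, unit="cell")
        mixture = gm.type_mixture(cells, smoothing_window=3)
        return gm.lineage_composition_null(cells, mixture, min_unique=2)

    null_ind = run(BurstParams(), s1)
    z_ind = gm.composition_zscores(null_ind)
    null_b = run(
        BurstParams(burst_lineage_prob=0.05, burst_size_mean=15), s2
    )
    z_big = gm.composition_zscores(null_b, min_size=10)
    others = z_big[z_big["cell_type"] != "ASC-3"]["z"]
    return {
        "independence_max_abs_z": float(z_ind["z"].abs().max()),
        "burst_asc3_z_large": float(
            z_big.loc[z_big["cell_type"] == "ASC-3", "z"].iloc[0]
        ),
        "burst_max_other_z_large": float(others.max()),
        "n_lineages_tested": int(len(null_ind.per_lineage)),
    }


def normalization_benchmark(seed: int, n_lineages: int = 3000) -> dict:
    """Self-normalization identity and capture-probability invariance.

    Sharing of a tissue with its own replicate emulsion normalizes to 1;
    halving the capture probability moves raw sharing and its replicate
    denominator together, leaving the normalized estimate unchanged within
    resampling error.
    """
    s1, s2 = _seeds(seed, 2, key=7)
    gc = GCParams(death_rate=0.076)
    # expanded clones large enough that per-emulsion detectability saturates;
    # the normalization is exactly thinning-invariant in that regime
    burst = BurstParams(burst_lineage_prob=0.05, burst_size_mean=60)
    res = simulate_truth(
        gc, _ONE_TISSUE, burst, n_lineages, 15, 0.0, s1, sequences=False
    )
    rec = sample_repertoire(
        res.cells, "d1", SamplingParams(emulsions_per_tissue=2), s1 + 1
    )
    # split the two emulsions into pseudo-tissues: target = replicate
    rec2 = rec.copy()
    rec2.loc[rec2["emulsion_id"] == "BM-e1", "tissue"] = "S1"
    rec2.loc[rec2["emulsion_id"] == "BM-e2", "tissue"] = "S2"
    n_unique = int(rec.groupby("emulsion_id")["vdj_key"].nunique().min() * 0.8)
    raw = tsh.sharing_probability(rec2, ("S1",), "S2", n_unique, 50, s1 + 2)
    norm = tsh.normalize_sharing(raw, rec, s1 + 3, denom_tissue="BM")
    out = {"replicate_normalized": float(norm.normalized)}

    # capture invariance on a two-tissue system with multi-tissue bursts
    loc2 = LocalizationParams(tissues=("Spleen", "Blood"), leak_prob=0.002)
    res2 = simulate_truth(
        gc, loc2, burst, n_lineages, 15, 0.0, s2, sequences=False
    )
    norms = {}
    for cap in (1.0, 0.5):
        rc = sample_repertoire(
            res2.cells,
            "d1",
            SamplingParams(emulsions_per_tissue=2, capture_prob=cap),
            s2 + 1,
        )
        nu = int(rc.groupby("emulsion_id")["vdj_key"].nunique().min() * 0.8)
        raw_c = tsh.sharing_probability(rc, ("Spleen",), "Blood", nu, 50, s2 + 2)
        est = tsh.normalize_sharing(raw_c, rc, s2 + 3)
        norms[cap] = {
            "raw": est.raw,
            "denominator": est.denominator,
            "normalized": est.normalized,
        }
    out["capture_full"] = norms[1.0]
    out["capture_half"] = norms[0.5]
    out["capture_invariance_absdiff"] = float(
        abs(norms[1.0]["normalized"] - norms[0.5]["normalized"])
    )
    return out


def simpson_benchmark(seed: int, n_lineages: int = 3000) -> dict:
    """Simpson's-paradox fixture: one dataset, two assertions.

    With lineage-level rate dispersion coupled to ASC-tilted composition,
    repertoire-level mean hypermutation differs between ASCs and memory
    cells while within-lineage relative hypermutation stays inside the
    cell-type permutation band.
    """
    gc = GCParams(
        death_rate=0.076,
        lineage_rate_dispersion=0.6,
        maturation_type_coupling=1.0,
    )
    res = simulate_truth(
        gc, _ONE_TISSUE, BurstParams(), n_lineages, 20, 0.0, seed,
        sequences=False,
    )
    cells = _truth_vdjs(res)
    pooled = cells.copy()
    pooled.loc[pooled["cell_type"].str.startswith("ASC"), "cell_type"] = "ASC"
    uniq = pooled.drop_duplicates(["vdj_key", "cell_type"])
    mean_asc = float(uniq.loc[uniq["cell_type"] == "ASC", "m"].mean())
    mean_mem = float(uniq.loc[uniq["cell_type"] == "Memory", "m"].mean())
    rel = ls.relative_levels(pooled, "cell_type", 5)
    bands = ls.permutation_band(rel, 100, seed + 1)
    cov = {
        t: float(ls.cdf_difference(rel, bands[t], t)["inside"].mean())
        for t in ("Memory", "ASC")
    }
    return {
        "mean_m_asc": mean_asc,
        "mean_m_memory": mean_mem,
        "mean_m_gap": mean_asc - mean_mem,
        "band_coverage": cov,
        "min_band_coverage": min(cov.values()),
    }


def mature_exit_benchmark(seed: int, n_founders: int = 200_000) -> dict:
    """Fraction of differentiated output created after rate stabilization.

    At a slow total event rate (Λ = 0.02, with 2x suppression of exits below
    10 hypermutations) most cells exit after their rates have stabilized.
    """
    rates = {"Memory": 0.0058, "ASC-1": 0.001, "ASC-2": 0.0008,
             "ASC-3": 0.0012, "ASC-4": 0.0012}
    gc = GCParams(
        exit_rates=rates, death_rate=0.01, suppression_factor=0.5, m_stab=10
    )
    res = simulate_truth(
        gc, _ONE_TISSUE, BurstParams(), 1, n_founders, 0.0, seed,
        founder_dist="fixed", sequences=False,
    )
    members = gm.differentiated_members(_truth_vdjs(res), min_m=0)
    frac = gm.fraction_mature_exits(members, 10)
    from .simulate import theoretical_summary

    return {
        "fraction_mature": frac,
        "theory": theoretical_summary(gc)["frac_mature_exits"],
        "n_exits": int(len(members.drop_duplicates("vdj_key"))),
    }
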