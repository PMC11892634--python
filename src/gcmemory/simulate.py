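"""Ground-truthed synthetic multi-tissue BCR repertoires.

The generative model: each lineage is founded by one or more naive-derived
founders that enter a germinal center.  In every cycle a cell first faces an
event draw — death, or exit as one of the differentiated cell types, each a
constant per-cycle probability — and, if it survives, accrues hypermutations.
The hypermutation count of an exiting cell is therefore geometric in the
total per-cycle event rate, the molecular-clock structure every downstream
estimator relies on.  Lineages carry a home tissue; exiting cells settle
there except for rare per-cell leakage, and burst-prone lineages expand one
of their clones into many identical ASC-3 cells.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import BurstParams, GCParams, LocalizationParams, SamplingParams

__all__ = [
    "SimulationResult",
    "simulate_truth",
    "sample_repertoire",
    "theoretical_summary",
    "write_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Synthetic germline gene pools.  Zipf-ish V usage, uniform J.
_V_GENES = [f"IGHV{f}-{i}" for f in range(1, 8) for i in range(1, 8)]
_V_WEIGHTS = np.array([1.0 / (k + 2) for k in range(len(_V_GENES))])
_V_WEIGHTS /= _V_WEIGHTS.sum()
_J_GENES = [f"IGHJ{i}" for i in range(1, 7)]


@dataclass
class SimulationResult:
    """Ground truth produced by :func:`simulate_truth`.

    Attributes
    ----------
    cells
        One row per true cell: lineage_id, cell_id, clone_id, cell_type, m,
        tissue, v_gene, j_gene and (when sequences are generated) junction_nt
        and sequence.  Cells sharing clone_id carry identical sequences.
    lineages
        Per-lineage sidecar: home tissue, rate multiplier, burst flag,
        naive flag, founder/exit/death tallies.
    attrition
        Founders discarded at the cycle cap (count and fraction).
    """

    cells: pd.DataFrame
    lineages: pd.DataFrame
    attrition: dict = field(default_factory=dict)


def _per_lineage_exit_rates(gc: GCParams, g: np.ndarray) -> np.ndarray:
    """(n_lineages, n_types) exit-rate matrix after the maturation-type tilt.

    The tilt multiplies ASC-type rates by g**-kappa and renormalizes so the
    total exit rate (hence the total event rate) is unchanged.
    """
    base = np.array([gc.exit_rates[t] for t in gc.types])
    n = len(g)
    rates = np.broadcast_to(base, (n, base.size)).copy()
    kappa = gc.maturation_type_coupling
    if kappa > 0:
        asc = np.array([t.startswith("ASC") for t in gc.types])
        if asc.any() and (~asc).any():
            tilt = np.power(g, -kappa)
            rates[:, asc] *= tilt[:, None]
            rates *= (base.sum() / rates.sum(axis=1))[:, None]
    return rates


def _draw_exit_cycles(
    rng: np.random.Generator,
    gc: GCParams,
    lam_low: np.ndarray,
    lam_high: np.ndarray,
) -> np.ndarray:
    """Cycle index (1-based) of each founder's event, two-phase geometric."""
    mu = gc.mutations_per_cycle
    s_cyc = 0
    if gc.suppression_factor < 1 and gc.m_stab > 0 and mu > 0:
        # cycles whose pre-event m (= mu*(cycle-1)) is below m_stab
        s_cyc = int(math.ceil(gc.m_stab / mu))
    t1 = rng.geometric(np.clip(lam_low, 1e-300, 1.0))
    if s_cyc == 0:
        return t1
    t2 = rng.geometric(np.clip(lam_high, 1e-300, 1.0))
    return np.where(t1 <= s_cyc, t1, s_cyc + t2)


def _draw_fates(
    rng: np.random.Generator,
    gc: GCParams,
    rates: np.ndarray,
    lin_of_founder: np.ndarray,
    low_phase: np.ndarray,
) -> np.ndarray:
    """Fate index per founder: 0..n_types-1 = exit type, n_types = death.

    Conditional on an event, the lineage multiplier cancels; the suppression
    factor reweights exits against death in the low phase.
    """
    n_types = rates.shape[1]
    f = gc.suppression_factor
    d = gc.death_rate
    uniform_rates = gc.maturation_type_coupling == 0

    def cond_cum(mat: np.ndarray, factor: float) -> np.ndarray:
        ex = mat * factor
        tot = ex.sum(axis=1, keepdims=True) + d
        probs = np.concatenate([ex, np.full((mat.shape[0], 1), d)], axis=1) / tot
        cum = np.cumsum(probs, axis=1)
        cum[:, -1] = 1.0
        return cum

    u = rng.random(lin_of_founder.size)
    if uniform_rates:
        cum_hi = cond_cum(rates[:1], 1.0)[0]
        cum_lo = cond_cum(rates[:1], f)[0] if f < 1 else cum_hi
        fate = np.searchsorted(cum_hi, u, side="right")
        if f < 1 and low_phase.any():
            fate[low_phase] = np.searchsorted(cum_lo, u[low_phase], side="right")
    else:
        cum_hi = cond_cum(rates, 1.0).astype(np.float32)
        rows = cum_hi[lin_of_founder]
        if f < 1:
            cum_lo = cond_cum(rates, f).astype(np.float32)
            rows = np.where(low_phase[:, None], cum_lo[lin_of_founder], rows)
        rows[:, -1] = 1.0
        fate = (u.astype(np.float32)[:, None] < rows).argmax(axis=1)
    return np.minimum(fate, n_types)


def _simulate_exits_poisson(
    rng: np.random.Generator,
    gc: GCParams,
    rates: np.ndarray,
    lin_of_founder: np.ndarray,
    g: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Cycle-by-cycle loop used when mutation accrual is Poisson."""
    n = lin_of_founder.size
    m = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    out_m = np.zeros(n, dtype=np.int64)
    out_fate = np.full(n, -1, dtype=np.int64)
    d = gc.death_rate
    f = gc.suppression_factor
    for _ in range(gc.max_cycles):
        if active.size == 0:
            break
        gl = g[lin_of_founder[active]]
        low = m[active] < gc.m_stab
        factor = np.where(low, f, 1.0)
        sum_exit = rates[lin_of_founder[active]].sum(axis=1)
        lam = gl * (factor * sum_exit + d)
        u = rng.random(active.size)
        event = u < lam
        idx = active[event]
        if idx.size:
            out_m[idx] = m[idx]
            out_fate[idx] = _draw_fates(
                rng, gc, rates, lin_of_founder[idx], m[idx] < gc.m_stab
            )
        active = active[~event]
        m[active] += rng.poisson(gc.mutations_per_cycle, active.size)
    discarded = active.size
    keep = out_fate >= 0
    return out_m[keep], out_fate[keep], lin_of_founder[keep], discarded


def simulate_truth(
    gc: GCParams,
    loc: LocalizationParams,
    burst: BurstParams,
    n_lineages: int,
    founders_per_lineage: int,
    naive_fraction: float,
    seed: int,
    *,
    founder_dist: str = "geometric",
    sequences: bool = True,
    junction_mut_rate: float = 0.02,
    v_length: int = 300,
    naive_clone_mean: float = 2.0,
    young_lineage_max_cycles: int | None = None,
) -> SimulationResult:
    """Simulate ground-truth cells under the constant-rate GC model.

    Parameters beyond the four parameter blocks:

    ``founders_per_lineage`` is the mean lineage founder count; with the
    default ``founder_dist="geometric"`` per-lineage counts are geometric
    with that mean (broad, realistic lineage sizes), with ``"fixed"`` every
    lineage gets exactly that many founders.  ``naive_fraction`` of lineages
    additionally emit unmutated naive cells (one clone of mean size
    ``naive_clone_mean``) that never enter the GC.  When
    ``young_lineage_max_cycles`` is set, naive-containing lineages are
    treated as recently founded: their exits beyond that cycle are discarded.
    ``sequences=False`` skips nucleotide-sequence synthesis (clone identity
    is still tracked through clone_id), which is much faster for large
    rate-inference simulations.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    if founders_per_lineage < 1:
        raise ValueError("founders_per_lineage must be >= 1")
    if not 0 <= naive_fraction <= 1:
        raise ValueError("naive_fraction must be a probability")
    if founder_dist not in ("geometric", "fixed"):
        raise ValueError(f"unknown founder_dist {founder_dist!r}")

    rng = np.random.default_rng(seed)
    tissues = list(loc.tissues)

    # --- lineage-level draws -------------------------------------------------
    if founder_dist == "fixed":
        n_found = np.full(n_lineages, founders_per_lineage, dtype=np.int64)
    else:
        n_found = rng.geometric(1.0 / founders_per_lineage, n_lineages)
    disp = gc.lineage_rate_dispersion
    if disp > 0:
        shape = 1.0 / disp**2
        g = rng.gamma(shape, disp**2, n_lineages)
        # keep the realized total event probability <= 1 per invariant
        g = np.minimum(g, 1.0 / gc.total_event_rate)
        g = np.maximum(g, 1e-6)
    else:
        g = np.ones(n_lineages)
    home_idx = rng.choice(len(tissues), size=n_lineages, p=loc.weights())
    naive_lin = rng.random(n_lineages) < naive_fraction
    burst_pool = ~naive_lin if burst.exclude_naive_lineages else np.ones(
        n_lineages, dtype=bool
    )
    burst_lin = (rng.random(n_lineages) < burst.burst_lineage_prob) & burst_pool
    v_idx = rng.choice(len(_V_GENES), size=n_lineages, p=_V_WEIGHTS)
    j_idx = rng.integers(0, len(_J_GENES), size=n_lineages)
    rates = _per_lineage_exit_rates(gc, g)

    # --- founder trajectories ------------------------------------------------
    lin_of_founder = np.repeat(np.arange(n_lineages), n_found)
    n_founders_total = int(lin_of_founder.size)
    sum_exit = rates.sum(axis=1)  # == gc.total_exit_rate for every lineage
    lam_high = g * (sum_exit + gc.death_rate)
    lam_low = g * (gc.suppression_factor * sum_exit + gc.death_rate)

    if gc.mutation_dist == "poisson":
        m_exit, fate, lin_exit, discarded = _simulate_exits_poisson(
            rng, gc, rates, lin_of_founder, g
        )
        cycles = m_exit + 1  # approximate; used only for young-lineage cap
    else:
        cyc = _draw_exit_cycles(
            rng, gc, lam_low[lin_of_founder], lam_high[lin_of_founder]
        )
        within_cap = cyc <= gc.max_cycles
        discarded = int((~within_cap).sum())
        mu = int(gc.mutations_per_cycle)
        low_phase = (mu * (cyc - 1)) < gc.m_stab
        fate_all = _draw_fates(rng, gc, rates, lin_of_founder, low_phase)
        keep = within_cap
        m_exit = (mu * (cyc[keep] - 1)).astype(np.int64)
        fate = fate_all[keep]
        lin_exit = lin_of_founder[keep]
        cycles = cyc[keep]

    n_types = len(gc.types)
    died = fate == n_types
    n_deaths = np.bincount(lin_exit[died], minlength=n_lineages)
    exited = ~died
    m_exit = m_exit[exited]
    fate = fate[exited]
    lin_exit = lin_exit[exited]
    cycles = cycles[exited]

    if young_lineage_max_cycles is not None:
        young_drop = naive_lin[lin_exit] & (cycles > young_lineage_max_cycles)
        discarded += int(young_drop.sum())
        m_exit, fate, lin_exit = (
            m_exit[~young_drop],
            fate[~young_drop],
            lin_exit[~young_drop],
        )

    # --- tissue localization -------------------------------------------------
    leak = loc.leak_map()
    cell_home = home_idx[lin_exit]
    tissue_idx = cell_home.copy()
    if leak:
        u = rng.random(lin_exit.size)
        for h, h_name in enumerate(tissues):
            others = [t for t in tissues if t != h_name]
            probs = np.array([leak.get((h_name, b), 0.0) for b in others])
            if probs.sum() == 0:
                continue
            cum = np.cumsum(probs)
            sel = cell_home == h
            moved = u[sel] < cum[-1]
            dest = np.searchsorted(cum, u[sel][moved], side="right")
            dest_idx = np.array([tissues.index(b) for b in others])[dest]
            tmp = tissue_idx[sel]
            tmp[moved] = dest_idx
            tissue_idx[sel] = tmp

    type_labels = np.array(list(gc.types) + ["Naive"])
    cell_lin = [lin_exit]
    cell_m = [m_exit]
    cell_type = [fate]
    cell_tissue = [tissue_idx]
    clone_id = [np.arange(lin_exit.size, dtype=np.int64)]
    next_clone = lin_exit.size

    # --- naive cells ---------------------------------------------------------
    naive_ids = np.flatnonzero(naive_lin)
    if naive_ids.size:
        sizes = 1 + rng.poisson(max(naive_clone_mean - 1.0, 0.0), naive_ids.size)
        lin_n = np.repeat(naive_ids, sizes)
        cid = np.repeat(np.arange(naive_ids.size) + next_clone, sizes)
        next_clone += naive_ids.size
        cell_lin.append(lin_n)
        cell_m.append(np.zeros(lin_n.size, dtype=np.int64))
        cell_type.append(np.full(lin_n.size, n_types, dtype=np.int64))
        cell_tissue.append(home_idx[lin_n])
        clone_id.append(cid)

    # --- ASC-3 bursts: expand an existing clone without hypermutation --------
    asc3 = list(gc.types).index("ASC-3") if "ASC-3" in gc.types else None
    burst_ids = np.flatnonzero(burst_lin)
    if burst_ids.size and asc3 is not None:
        exits_by_lin = pd.Series(np.arange(lin_exit.size)).groupby(lin_exit).groups
        for lid in burst_ids:
            members = exits_by_lin.get(lid)
            if members is None or len(members) == 0:
                continue
            for _ in range(burst.clones_per_lineage):
                tpl = int(rng.choice(np.asarray(members)))
                size = int(rng.geometric(1.0 / burst.burst_size_mean))
                if burst.multi_tissue_burst:
                    tis = rng.integers(0, len(tissues), size)
                else:
                    tis = np.full(size, home_idx[lid])
                cell_lin.append(np.full(size, lid, dtype=np.int64))
                cell_m.append(np.full(size, m_exit[tpl], dtype=np.int64))
                cell_type.append(np.full(size, asc3, dtype=np.int64))
                cell_tissue.append(tis)
                clone_id.append(np.full(size, clone_id[0][tpl], dtype=np.int64))

    lin_all = np.concatenate(cell_lin)
    cells = pd.DataFrame(
        {
            "lineage_id": lin_all,
            "clone_id": np.concatenate(clone_id),
            "cell_type": type_labels[np.concatenate(cell_type)],
            "m": np.concatenate(cell_m),
            "tissue": np.array(tissues)[np.concatenate(cell_tissue)],
            "v_gene": np.array(_V_GENES)[v_idx[lin_all]],
            "j_gene": np.array(_J_GENES)[j_idx[lin_all]],
        }
    )
    cells.insert(1, "cell_id", np.arange(len(cells), dtype=np.int64))

    if sequences:
        _attach_sequences(rng, cells, n_lineages, junction_mut_rate, v_length)

    n_exits = np.bincount(lin_exit, minlength=n_lineages)
    lineages = pd.DataFrame(
        {
            "lineage_id": np.arange(n_lineages),
            "home_tissue": np.array(tissues)[home_idx],
            "rate_multiplier": g,
            "burst_prone": burst_lin,
            "has_naive": naive_lin,
            "n_founders": n_found,
            "n_exits": n_exits,
            "n_deaths": n_deaths,
            "v_gene": np.array(_V_GENES)[v_idx],
            "j_gene": np.array(_J_GENES)[j_idx],
        }
    )
    attrition = {
        "n_discarded": int(discarded),
        "n_founders": n_founders_total,
        "frac_discarded": discarded / max(n_founders_total, 1),
    }
    return SimulationResult(cells=cells, lineages=lineages, attrition=attrition)


def _mutate_rows(
    rng: np.random.Generator, founder: np.ndarray, n_mut: np.ndarray
) -> np.ndarray:
    """Copy a founder base-code vector into rows and apply per-row mutations."""
    nc = n_mut.size
    mat = np.broadcast_to(founder, (nc, founder.size)).copy()
    total = int(n_mut.sum())
    if total:
        rows = np.repeat(np.arange(nc), n_mut)
        pos = rng.integers(0, founder.size, total)
        shift = rng.integers(1, 4, total)
        mat[rows, pos] = (mat[rows, pos] + shift) % 4
    return mat


def _attach_sequences(
    rng: np.random.Generator,
    cells: pd.DataFrame,
    n_lineages: int,
    junction_mut_rate: float,
    v_length: int,
) -> None:
    """Synthesize per-clone junction and full (V + junction) sequences.

    One founder junction (random, length 30-60 nt) and one founder V region
    per lineage; each clone carries the founder junction with independent
    per-site mutations at ``junction_mut_rate`` and a V region with its
    annotated hypermutation count applied at random sites.  Clones of one
    lineage that end up with identical sequences (e.g. unmutated naive
    clones and m=0 exits) are merged into a single clone.
    """
    clones = (
        cells[["lineage_id", "clone_id", "m"]]
        .drop_duplicates("clone_id")
        .sort_values("clone_id")
        .reset_index(drop=True)
    )
    j_len = rng.integers(30, 61, n_lineages)
    junctions = np.empty(len(clones), dtype=object)
    seqs = np.empty(len(clones), dtype=object)
    for lid, grp in clones.groupby("lineage_id", sort=True):
        founder_j = rng.integers(0, 4, j_len[lid])
        founder_v = rng.integers(0, 4, v_length)
        nc = len(grp)
        jmat = _mutate_rows(
            rng, founder_j, rng.binomial(founder_j.size, junction_mut_rate, nc)
        )
        vmat = _mutate_rows(rng, founder_v, grp["m"].to_numpy())
        jb = _BASES[jmat]
        vb = _BASES[vmat]
        for k, row in enumerate(grp.index):
            junctions[row] = jb[k].tobytes().decode("ascii")
            seqs[row] = vb[k].tobytes().decode("ascii") + junctions[row]
    clones["junction_nt"] = junctions
    clones["sequence"] = seqs

    # merge duplicate sequences within a lineage into one clone
    first = clones.groupby(["lineage_id", "sequence", "m"])["clone_id"].transform(
        "min"
    )
    remap = dict(zip(clones["clone_id"], first))
    clones["clone_id"] = first
    clones = clones.drop_duplicates("clone_id")
    cells["clone_id"] = cells["clone_id"].map(remap)
    merged = cells.merge(
        clones[["clone_id", "junction_nt", "sequence"]], on="clone_id", how="left"
    )
    cells["junction_nt"] = merged["junction_nt"].to_numpy()
    cells["sequence"] = merged["sequence"].to_numpy()


def theoretical_summary(gc: GCParams) -> dict:
    """Closed-form expectations for the constant-rate model (zero dispersion).

    Returns the plateau event rate Λ, the suppressed-phase rate Λ_low, the
    unconditional probability of exiting with m < m_stab, and per exit type
    the exit-type mixture p_t = r_t/Σr, the mean hypermutation count of
    exiting cells, and the fraction of exits with m >= m_stab.
    """
    if gc.lineage_rate_dispersion != 0:
        raise ValueError(
            "theoretical_summary requires zero lineage_rate_dispersion: "
            "the geometric closed form is exact only without heterogeneity"
        )
    sum_exit = gc.total_exit_rate
    lam = gc.total_event_rate
    lam_low = gc.low_event_rate
    f = gc.suppression_factor
    s = gc.m_stab if f < 1 else 0
    mu = gc.mutations_per_cycle

    if gc.mutation_dist == "poisson":
        if f < 1:
            raise ValueError("Poisson closed form implemented only at suppression 1")
        # m | exit is a geometric mixture of Poissons; summed numerically
        kmax = max(int(50 / lam), 100)
        c = np.arange(kmax)
        w = lam * (1 - lam) ** c
        w /= w.sum()
        mean_m = float((w * mu * c).sum())
        from scipy.stats import poisson

        frac_mature = float((w * poisson.sf(gc.m_stab - 1, np.maximum(mu * c, 1e-12))).sum())
    else:
        mu_i = int(mu)
        s_cyc = int(math.ceil(s / mu_i)) if (s > 0 and mu_i > 0) else 0
        kmax = max(int(math.ceil(-40 / math.log1p(-min(lam, 0.999999)))), s_cyc + 10)
        cyc = np.arange(1, kmax + 1)
        low = cyc <= s_cyc
        # P(exit at cycle c): survive c-1 cycles, then an exit event
        surv = np.concatenate(
            [[1.0], np.cumprod(np.where(low, 1 - lam_low, 1 - lam))]
        )[:-1]
        p_exit_at = surv * np.where(low, f * sum_exit, sum_exit)
        m_at = mu_i * (cyc - 1)
        p_exit = float(p_exit_at.sum())
        mean_m = float((p_exit_at * m_at).sum() / p_exit)
        frac_mature = float(p_exit_at[m_at >= gc.m_stab].sum() / p_exit)

    p_exit_low = (sum_exit * f / lam_low) * (1 - (1 - lam_low) ** s) if s else 0.0
    out = {
        "lambda_total": lam,
        "lambda_low": lam_low,
        "p_exit_low_m": float(p_exit_low),
        "frac_mature_exits": frac_mature,
        "types": {},
    }
    for t in gc.types:
        p_t = gc.exit_rates[t] / sum_exit
        out["types"][t] = {
            "p_type": p_t,
            "mean_m": mean_m,  # identical across types: fate draw is m-independent
            "frac_mature": frac_mature,
        }
    return out


def sample_repertoire(
    truth: pd.DataFrame,
    donor: str,
    sp: SamplingParams,
    seed: int,
) -> pd.DataFrame:
    """Emulsion-sample true cells into observed cell records.

    Cells are partitioned by tissue, captured independently with
    ``sp.capture_prob``, and assigned uniformly to one of
    ``sp.emulsions_per_tissue`` emulsions per tissue.  Returns the cell-record
    table (one row per sampled cell) with vdj_key = true clone identity and
    the true lineage retained in ``true_lineage_id`` for validation.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(seed)
    out = []
    for tissue in sorted(truth["tissue"].unique()):
        sub = truth[truth["tissue"] == tissue]
        kept = sub[rng.random(len(sub)) < sp.capture_prob]
        if len(kept) == 0:
            warnings.warn(f"tissue {tissue!r} yielded zero sampled cells")
            continue
        emul = rng.integers(0, sp.emulsions_per_tissue, len(kept))
        kept = kept.assign(
            emulsion_id=[f"{tissue}-e{e + 1}" for e in emul], donor=donor
        )
        if sp.cells_per_emulsion > 0:
            kept = (
                kept.groupby("emulsion_id", group_keys=False)
                .apply(
                    lambda df: df.sample(
                        min(len(df), sp.cells_per_emulsion),
                        random_state=int(rng.integers(2**31)),
                    ),
                    include_groups=True,
                )
                .reset_index(drop=True)
            )
        out.append(kept)
    if not out:
        warnings.warn("no cells sampled from any tissue")
        cols = list(truth.columns) + ["emulsion_id", "donor"]
        return pd.DataFrame(columns=cols)
    rec = pd.concat(out, ignore_index=True)
    iso = np.where(
        rec["cell_type"] == "Naive",
        "IGHM",
        np.array(["IGHM", "IGHG1", "IGHA1"])[
            rng.choice(3, len(rec), p=[0.2, 0.5, 0.3])
        ],
    )
    rec["isotype"] = iso
    rec = rec.rename(columns={"clone_id": "vdj_key", "lineage_id": "true_lineage_id"})
    order = [
        "cell_id",
        "donor",
        "tissue",
        "emulsion_id",
        "cell_type",
        "isotype",
        "vdj_key",
        "v_gene",
        "j_gene",
        "m",
        "true_lineage_id",
    ]
    for c in ("junction_nt", "sequence"):
        if c in rec.columns:
            order.insert(9, c)
    return rec[order].sort_values("cell_id").reset_index(drop=True)


def write_truth(
    records: pd.DataFrame, path: str, lineages: pd.DataFrame | None = None
) -> dict[str, str]:
    """Write the AIRR + metadata TSV pair plus ground-truth sidecars.

    ``records`` must come from :func:`sample_repertoire` with sequences
    enabled.  Returns the paths written.
    """
    if "sequence" not in records.columns or records["sequence"].isna().any():
        raise ValueError(
            "records lack nucleotide sequences; rerun the simulation with "
            "sequences=True before writing"
        )
    os.makedirs(path, exist_ok=True)
    paths = {}
    airr = pd.DataFrame(
        {
            "sequence_id": [f"cell{c}_contig-1" for c in records["cell_id"]],
            "cell_id": records["cell_id"],
            "v_call": records["v_gene"],
            "j_call": records["j_gene"],
            "junction": records["junction_nt"],
            "sequence": records["sequence"],
            "v_mutation_count": records["m"],
        }
    )
    paths["airr"] = os.path.join(path, "airr.tsv")
    airr.to_csv(paths["airr"], sep="\t", index=False)

    meta = records[
        ["cell_id", "donor", "tissue", "emulsion_id", "cell_type", "isotype"]
    ]
    paths["meta"] = os.path.join(path, "meta.tsv")
    meta.to_csv(paths["meta"], sep="\t", index=False)

    truth_cells = records[["cell_id", "vdj_key", "true_lineage_id", "m"]]
    paths["truth_cells"] = os.path.join(path, "truth_cells.tsv")
    truth_cells.to_csv(paths["truth_cells"], sep="\t", index=False)

    if lineages is not None:
        paths["truth_lineages"] = os.path.join(path, "truth_lineages.tsv")
        lineages.to_csv(paths["truth_lineages"], sep="\t", index=False)
    return paths
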