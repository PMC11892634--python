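"""Effective germinal-center exit rates and composition nulls.

Under the constant-rate model, the hypermutation count m of a cell exiting
the germinal center is geometric in the total per-cycle event rate Λ, and
the per-cycle exit rate into type t can be estimated as a hazard from the
pooled hypermutation histogram:

    lambda_hat_t(m) = C_t(m) / S(m),

with C_t(m) the number of unique VDJs of type t at exactly m mutations and
S(m) the number of unique VDJs of any differentiated type at >= m.  Because
dead cells are unobservable, lambda_hat_t estimates r_t * Λ / Σr — absolute
rates only up to a common factor — so all reported quantities are ratios or
plateau-scaled curves, which are invariant to that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HazardCurve",
    "PlateauRates",
    "TypeMixture",
    "CompositionNull",
    "differentiated_members",
    "exit_hazard",
    "plateau_rates",
    "scaled_hazard",
    "type_mixture",
    "model_mixture",
    "lineage_composition_null",
    "composition_zscores",
    "fraction_mature_exits",
]

#: Cell types that never represent a germinal-center differentiation outcome.
NON_DIFFERENTIATED = ("Naive", "GC", "Unknown")


@dataclass
class HazardCurve:
    cell_type: str
    m: np.ndarray
    lambda_hat: np.ndarray
    counts: np.ndarray  # C_t(m)
    at_risk: np.ndarray  # S(m)
    se: np.ndarray
    masked: np.ndarray

    def unmasked(self) -> pd.DataFrame:
        keep = ~self.masked
        return pd.DataFrame(
            {
                "m": self.m[keep],
                "lambda_hat": self.lambda_hat[keep],
                "se": self.se[keep],
            }
        )


@dataclass
class PlateauRates:
    """Long-term (plateau) exit rates and their pairwise ratios."""

    rates: dict[str, float]
    ratios: dict[str, dict[str, float]]
    m_stab: int
    counts: dict[str, float] = field(default_factory=dict)

    def ratio(self, a: str, b: str) -> float:
        return self.ratios[a][b]


@dataclass
class TypeMixture:
    """p_t(m): probability vector over differentiated types at each m."""

    types: list[str]
    m: np.ndarray
    probs: np.ndarray  # (len(m), len(types)); NaN rows where undefined
    counts: np.ndarray  # raw member counts per (m, type), unsmoothed
    smoothing_window: int

    def lookup(self, m_values: np.ndarray) -> np.ndarray:
        """p_t rows for arbitrary m, mapped to the nearest defined bin."""
        defined = ~np.isnan(self.probs).any(axis=1)
        grid = self.m[defined]
        if grid.size == 0:
            raise ValueError("mixture has no defined bins")
        idx = np.clip(np.searchsorted(grid, m_values), 0, grid.size - 1)
        left = np.clip(idx - 1, 0, grid.size - 1)
        use_left = np.abs(grid[left] - m_values) <= np.abs(grid[idx] - m_values)
        nearest = np.where(use_left, left, idx)
        return self.probs[defined][nearest]


def differentiated_members(
    records: pd.DataFrame,
    *,
    min_m: int = 1,
    unit: str = "vdj",
    pool_asc: bool = False,
) -> pd.DataFrame:
    """Members entering rate/composition analyses.

    Restricts to differentiated cell types (Naive/GC/Unknown excluded) with
    m >= ``min_m``.  ``unit="vdj"`` collapses to unique (vdj_key, cell_type)
    pairs — the default counting unit, which suppresses clonal-expansion
    weighting; ``unit="cell"`` keeps cells.  ``pool_asc`` merges ASC-1..4
    into a single ASC class.
    """
    if unit not in ("vdj", "cell"):
        raise ValueError("unit must be 'vdj' or 'cell'")
    sub = records[
        ~records["cell_type"].isin(NON_DIFFERENTIATED) & (records["m"] >= min_m)
    ].copy()
    if pool_asc:
        sub.loc[sub["cell_type"].str.startswith("ASC"), "cell_type"] = "ASC"
    if unit == "vdj":
        sub = sub.drop_duplicates(["vdj_key", "cell_type"])
    return sub


def exit_hazard(
    members: pd.DataFrame,
    m_max: int | None = None,
    min_bin_cells: int = 10,
) -> dict[str, HazardCurve]:
    """Per-type effective exit-rate curves lambda_hat_t(m).

    ``members`` is the output of :func:`differentiated_members`.  Bins where
    the total member count at that m falls below ``min_bin_cells`` (default
    10) are masked, as are bins with an empty risk set.
    """
    if len(members) == 0:
        raise ValueError("no differentiated members")
    m_vals = members["m"].to_numpy()
    if m_max is None:
        m_max = int(m_vals.max())
    types = sorted(members["cell_type"].unique())
    grid = np.arange(int(m_vals.min()), m_max + 1)
    hist = np.bincount(m_vals, minlength=int(m_vals.max()) + 1)
    # S(m): members of any type with >= m mutations (beyond m_max included)
    revcum = np.cumsum(hist[::-1])[::-1]
    total_at = hist[grid]
    at_risk = revcum[grid]
    curves = {}
    for t in types:
        mt = m_vals[members["cell_type"].to_numpy() == t]
        counts = np.bincount(mt, minlength=int(m_vals.max()) + 1)[grid]
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(at_risk > 0, counts / np.maximum(at_risk, 1), np.nan)
            se = np.sqrt(np.clip(lam * (1 - lam), 0, None) / np.maximum(at_risk, 1))
        masked = (total_at < min_bin_cells) | (at_risk == 0)
        curves[t] = HazardCurve(
            cell_type=t,
            m=grid.copy(),
            lambda_hat=lam,
            counts=counts,
            at_risk=at_risk.copy(),
            se=se,
            masked=masked,
        )
    return curves


def plateau_rates(
    hazards: dict[str, HazardCurve], m_stab: int = 10
) -> PlateauRates:
    """Count-weighted mean hazard over unmasked bins with m >= m_stab.

    The weighting by the risk set makes the plateau rate the exact pooled
    estimate sum C_t / sum S over the plateau region.
    """
    rates, counts = {}, {}
    for t, h in hazards.items():
        sel = (h.m >= m_stab) & ~h.masked
        if not sel.any():
            raise ValueError(
                f"no unmasked hazard bins at m >= {m_stab} for type {t!r}"
            )
        rates[t] = float(h.counts[sel].sum() / h.at_risk[sel].sum())
        counts[t] = float(h.counts[sel].sum())
    ratios = {
        a: {b: (rates[a] / rates[b] if rates[b] > 0 else np.inf) for b in rates}
        for a in rates
    }
    return PlateauRates(rates=rates, ratios=ratios, m_stab=m_stab, counts=counts)


def scaled_hazard(
    hazards: dict[str, HazardCurve], plateaus: PlateauRates
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Hazards divided by each type's plateau rate, plus cross-type spread.

    Returns per-type frames [m, scaled, se, masked] and a frame of the
    per-m spread (max - min of unmasked scaled values across types), the
    statistic behind the equal-multiplicative-suppression observation.
    """
    missing = set(hazards) - set(plateaus.rates)
    if missing:
        raise ValueError(f"plateau rates missing for types {sorted(missing)}")
    curves = {}
    stack = []
    for t, h in hazards.items():
        p = plateaus.rates[t]
        if p <= 0:
            raise ValueError(f"zero plateau rate for type {t!r}")
        curves[t] = pd.DataFrame(
            {
                "m": h.m,
                "scaled": h.lambda_hat / p,
                "se": h.se / p,
                "masked": h.masked,
            }
        )
        stack.append(np.where(h.masked, np.nan, h.lambda_hat / p))
    arr = np.vstack(stack)
    any_defined = ~np.isnan(arr).all(axis=0)
    spread = np.full(arr.shape[1], np.nan)
    if any_defined.any():
        sub = arr[:, any_defined]
        spread[any_defined] = np.nanmax(sub, axis=0) - np.nanmin(sub, axis=0)
    any_type = next(iter(hazards.values()))
    spread_df = pd.DataFrame({"m": any_type.m, "spread": spread})
    return curves, spread_df


def type_mixture(members: pd.DataFrame, smoothing_window: int = 3) -> TypeMixture:
    """Empirical p_t(m) with centered moving-window count smoothing.

    ``smoothing_window`` must be odd; 1 means no smoothing.  Bins with no
    members inside the window are left undefined (NaN).
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    if len(members) == 0:
        raise ValueError("no members")
    types = sorted(members["cell_type"].unique())
    grid = np.arange(members["m"].min(), members["m"].max() + 1)
    counts = np.zeros((grid.size, len(types)))
    tab = members.groupby(["m", "cell_type"]).size()
    for (m, t), n in tab.items():
        counts[int(m - grid[0]), types.index(t)] = n
    half = smoothing_window // 2
    kernel = np.ones(smoothing_window)
    smoothed = np.vstack(
        [np.convolve(counts[:, k], kernel, mode="same") for k in range(len(types))]
    ).T
    row_tot = smoothed.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_tot > 0, smoothed / row_tot, np.nan)
    return TypeMixture(
        types=types,
        m=grid,
        probs=probs,
        counts=counts,
        smoothing_window=smoothing_window,
    )


def model_mixture(
    plateaus: PlateauRates, m_grid: np.ndarray, types: list[str] | None = None
) -> TypeMixture:
    """Constant-rate model mixture: p_t(m) = plateau_t / sum(plateau).

    Constant in m — the expected type composition when per-cycle exit rates
    equal the long-term rates at every hypermutation level.
    """
    types = list(plateaus.rates) if types is None else types
    vec = np.array([plateaus.rates[t] for t in types], dtype=float)
    vec = vec / vec.sum()
    grid = np.asarray(m_grid)
    return TypeMixture(
        types=types,
        m=grid,
        probs=np.tile(vec, (grid.size, 1)),
        counts=np.zeros((grid.size, len(types))),
        smoothing_window=1,
    )


@dataclass
class CompositionNull:
    """Independence-null predictions of lineage cell-type composition."""

    per_lineage: pd.DataFrame  # lineage_id, size, per-type obs/exp columns
    by_size: pd.DataFrame  # size-binned observed vs expected fractions
    types: list[str]
    n_remapped: int  # members whose m fell outside the mixture support


def lineage_composition_null(
    members: pd.DataFrame,
    mixture: TypeMixture,
    min_unique: int = 2,
    min_cells: int = 6,
    min_lineages: int = 10,
) -> CompositionNull:
    """Predict lineage type content assuming independent member fates.

    For a lineage with member hypermutation counts {m_i}, the null gives
    P(contains type t) = 1 - prod_i (1 - p_t(m_i)) and an expected type-t
    fraction mean_i p_t(m_i).  Lineages need at least ``min_unique`` typed
    hypermutated unique VDJs; size-binned points supported by fewer than
    ``min_cells`` members or ``min_lineages`` lineages are omitted.
    """
    if "lineage_id" not in members.columns:
        raise ValueError("members need a lineage_id column")
    df = members.copy()
    nuniq = df.groupby("lineage_id")["vdj_key"].transform("nunique")
    df = df[nuniq >= min_unique]
    if len(df) == 0:
        raise ValueError("no lineages pass the min_unique filter")
    m = df["m"].to_numpy()
    defined = ~np.isnan(mixture.probs).any(axis=1)
    support = mixture.m[defined]
    n_remapped = int(((m < support.min()) | (m > support.max())).sum())
    P = mixture.lookup(m)  # (n_members, n_types)
    types = mixture.types
    out = []
    for lid, idx in df.groupby("lineage_id").indices.items():
        p = P[idx]
        obs_types = df["cell_type"].to_numpy()[idx]
        row = {"lineage_id": lid, "size": len(idx)}
        for k, t in enumerate(types):
            row[f"obs_{t}"] = int((obs_types == t).sum())
            row[f"exp_{t}"] = float(p[:, k].sum())
            row[f"var_{t}"] = float((p[:, k] * (1 - p[:, k])).sum())
            row[f"p_contains_{t}"] = float(1 - np.prod(1 - p[:, k]))
            row[f"contains_{t}"] = bool((obs_types == t).any())
        out.append(row)
    per_lineage = pd.DataFrame(out)

    sizes = per_lineage["size"]
    edges = [2, 3, 5, 9, 17, 33, 65, np.inf]
    bin_idx = np.digitize(sizes, edges[1:], right=False)
    rows = []
    for b in np.unique(bin_idx):
        sub = per_lineage[bin_idx == b]
        n_cells = int(sub["size"].sum())
        for t in types:
            if n_cells < min_cells or len(sub) < min_lineages:
                continue
            rows.append(
                {
                    "size_bin_low": edges[b],
                    "n_lineages": len(sub),
                    "n_cells": n_cells,
                    "cell_type": t,
                    "obs_frac": sub[f"obs_{t}"].sum() / n_cells,
                    "exp_frac": sub[f"exp_{t}"].sum() / n_cells,
                    "obs_contains": sub[f"contains_{t}"].mean(),
                    "exp_contains": sub[f"p_contains_{t}"].mean(),
                }
            )
    return CompositionNull(
        per_lineage=per_lineage,
        by_size=pd.DataFrame(rows),
        types=list(types),
        n_remapped=n_remapped,
    )


def composition_zscores(
    null: CompositionNull, min_size: int = 1
) -> pd.DataFrame:
    """Observed-minus-expected z-score per type over lineages >= min_size.

    z = (sum obs - sum exp) / sqrt(sum var) under the independence null.
    """
    sub = null.per_lineage[null.per_lineage["size"] >= min_size]
    rows = []
    for t in null.types:
        obs = sub[f"obs_{t}"].sum()
        exp = sub[f"exp_{t}"].sum()
        var = sub[f"var_{t}"].sum()
        rows.append(
            {
                "cell_type": t,
                "observed": obs,
                "expected": exp,
                "z": (obs - exp) / np.sqrt(var) if var > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fraction_mature_exits(members: pd.DataFrame, m_stab: int = 10) -> float:
    """Fraction of unique differentiated VDJs at m >= m_stab.

    The share of germinal-center output created after the exit rates have
    stabilized; computed over all differentiated unique VDJs (m >= 0).
    """
    uniq = members.drop_duplicates("vdj_key")
    if len(uniq) == 0:
        raise ValueError("no differentiated members")
    return float((uniq["m"] >= m_stab).mean())
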