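"""Tissue privacy, Poisson discovery curves, clone sizes, sharing estimates.

Lineage dispersal between tissues behaves like a Poisson process: a lineage
occupying a fraction x of an ascertainment tissue's unique VDJs is found in
a second tissue with probability 1 - exp(-x/x_c), with a single critical
size x_c per tissue pair.  Clone sharing between tissues is estimated on
emulsions downsampled to equal unique-VDJ counts and normalized by the
empirical probability of re-encountering a VDJ in an independent emulsion
of the same tissue, which conditions on expansion/detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .repertoire import downsample_emulsions

__all__ = [
    "XcFit",
    "SharingEstimate",
    "privacy_fractions",
    "discovery_curve",
    "fit_xc",
    "fit_xc_binned",
    "clone_size_distribution",
    "sharing_probability",
    "normalize_sharing",
]


@dataclass
class XcFit:
    """Maximum-likelihood fit of P(found | x) = 1 - exp(-x / x_c)."""

    ascertain: str
    target: str
    x_c: float
    ci: tuple[float, float]
    n_points: int
    loglik: float


@dataclass
class SharingEstimate:
    """Raw and replicate-normalized cross-tissue VDJ sharing probability."""

    source_set: tuple[str, ...]
    target: str
    raw: float
    raw_se: float
    n_resamples: int
    n_unique: int
    denominator: float | None = None
    denominator_se: float | None = None
    normalized: float | None = None
    extras: dict = field(default_factory=dict)


def privacy_fractions(
    records: pd.DataFrame, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Fraction of lineages private to each tissue, vs well-mixed expectation.

    Tissues are first downsampled to the same overall cell count; the
    expectation is obtained by permuting tissue labels over cells n_perm
    times.  Returns [tissue, n_lineages, fraction_private, expected_private].
    """
    if "lineage_id" not in records.columns:
        raise ValueError("records need a lineage_id column")
    tissues = sorted(records["tissue"].unique())
    if len(tissues) < 2:
        raise ValueError("privacy requires at least two tissues")
    rng = np.random.default_rng(seed)
    n_min = records.groupby("tissue").size().min()
    parts = []
    for t in tissues:
        sub = records[records["tissue"] == t]
        idx = rng.choice(len(sub), size=n_min, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    ds = pd.concat(parts, ignore_index=True)

    def private_fracs(tissue_labels: np.ndarray) -> dict[str, float]:
        df = pd.DataFrame(
            {"lineage_id": ds["lineage_id"].to_numpy(), "tissue": tissue_labels}
        )
        ntis = df.groupby("lineage_id")["tissue"].nunique()
        out = {}
        for t in tissues:
            lins = df.loc[df["tissue"] == t, "lineage_id"].unique()
            out[t] = float((ntis.loc[lins] == 1).mean())
        return out

    measured = private_fracs(ds["tissue"].to_numpy())
    perm_sum = {t: 0.0 for t in tissues}
    labels = ds["tissue"].to_numpy()
    for _ in range(n_perm):
        perm = private_fracs(rng.permutation(labels))
        for t in tissues:
            perm_sum[t] += perm[t]
    rows = [
        {
            "tissue": t,
            "n_cells": int(n_min),
            "fraction_private": measured[t],
            "expected_private": perm_sum[t] / n_perm,
        }
        for t in tissues
    ]
    return pd.DataFrame(rows)


def discovery_curve(
    records: pd.DataFrame,
    ascertain: str,
    target: str,
    n_unique: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """One point per lineage: size x in the ascertainment tissue, found flag.

    Emulsions of both tissues are downsampled to ``n_unique`` unique VDJs
    (smaller emulsions dropped); x is the lineage's fraction of the pooled
    downsampled ascertainment-tissue unique VDJs, found indicates >= 1
    unique VDJ in the downsampled target tissue.
    """
    if "lineage_id" not in records.columns:
        raise ValueError("records need a lineage_id column")
    sub = records[records["tissue"].isin([ascertain, target])]
    ds = downsample_emulsions(sub, n_unique, seed)
    asc = ds[ds["tissue"] == ascertain]
    if len(asc) == 0:
        raise ValueError(
            f"ascertainment tissue {ascertain!r} has no emulsion with "
            f">= {n_unique} unique VDJs"
        )
    uniq_a = asc.drop_duplicates("vdj_key")
    n_a = len(uniq_a)
    per_lin = uniq_a.groupby("lineage_id").size()
    target_lineages = set(ds.loc[ds["tissue"] == target, "lineage_id"].unique())
    out = pd.DataFrame(
        {
            "lineage_id": per_lin.index,
            "x": per_lin.to_numpy() / n_a,
            "found": [lid in target_lineages for lid in per_lin.index],
        }
    ).reset_index(drop=True)
    out.attrs["n_unique_ascertain"] = n_a
    out.attrs["ascertain"] = ascertain
    out.attrs["target"] = target
    return out


def _neg_loglik(log_xc: float, x: np.ndarray, found: np.ndarray) -> float:
    rate = x / np.exp(log_xc)
    with np.errstate(divide="ignore"):
        ll_found = np.log(-np.expm1(-rate[found]))
    return -(ll_found.sum() - rate[~found].sum())


def fit_xc(points: pd.DataFrame) -> XcFit:
    """Binomial MLE of the critical size x_c on unbinned discovery points.

    The likelihood treats each lineage as an independent Bernoulli trial
    with success probability 1 - exp(-x/x_c).  The confidence interval is
    the 95% profile-likelihood interval.  Errors if x_c is unidentifiable
    (fewer than 10 points, or all/none found).
    """
    if len(points) < 10:
        raise ValueError("need at least 10 discovery points")
    x = points["x"].to_numpy(dtype=float)
    found = points["found"].to_numpy(dtype=bool)
    if (x <= 0).any() or (x > 1).any():
        raise ValueError("x must lie in (0, 1]")
    if found.all() or not found.any():
        raise ValueError("x_c is not identifiable: all points share one outcome")
    lo, hi = np.log(x.min()) - 12.0, np.log(x.max()) + 12.0
    res = minimize_scalar(
        _neg_loglik, bounds=(lo, hi), args=(x, found), method="bounded",
        options={"xatol": 1e-10},
    )
    log_xc = float(res.x)
    ll_max = -float(res.fun)

    def drop(lv: float) -> float:
        return (-_neg_loglik(lv, x, found)) - (ll_max - 1.9207)

    ci_lo = np.exp(brentq(drop, lo, log_xc)) if drop(lo) < 0 else np.exp(lo)
    ci_hi = np.exp(brentq(drop, log_xc, hi)) if drop(hi) < 0 else np.exp(hi)
    return XcFit(
        ascertain=points.attrs.get("ascertain", ""),
        target=points.attrs.get("target", ""),
        x_c=float(np.exp(log_xc)),
        ci=(float(ci_lo), float(ci_hi)),
        n_points=len(points),
        loglik=ll_max,
    )


def fit_xc_binned(points: pd.DataFrame, n_bins: int = 10) -> float:
    """Diagnostic alternative: least squares on log-binned mean found rates."""
    x = points["x"].to_numpy(dtype=float)
    found = points["found"].to_numpy(dtype=float)
    edges = np.geomspace(x.min(), x.max() * (1 + 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    xs, ps, ws = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(x[sel].mean())
        ps.append(found[sel].mean())
        ws.append(sel.sum())
    xs, ps, ws = map(np.asarray, (xs, ps, ws))

    def sse(log_xc: float) -> float:
        pred = -np.expm1(-xs / np.exp(log_xc))
        return float((ws * (ps - pred) ** 2).sum())

    res = minimize_scalar(
        sse, bounds=(np.log(x.min()) - 12, np.log(x.max()) + 12), method="bounded"
    )
    return float(np.exp(res.x))


def clone_size_distribution(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-(type, tissue) clone-size histogram and overall expanded fraction.

    A clone is the set of cells with one VDJ in one tissue and cell type;
    the expanded fraction is the share of unique VDJs observed in more than
    one cell overall.
    """
    sizes = (
        records.groupby(["cell_type", "tissue", "vdj_key"])
        .size()
        .rename("clone_size")
        .reset_index()
    )
    hist = (
        sizes.groupby(["cell_type", "tissue", "clone_size"])
        .size()
        .rename("n_clones")
        .reset_index()
    )
    per_vdj = records.groupby("vdj_key").size()
    expanded_fraction = float((per_vdj > 1).mean())
    return hist, expanded_fraction


def _presence_sets(ds: pd.DataFrame) -> dict[str, set]:
    return {
        t: set(sub["vdj_key"].unique()) for t, sub in ds.groupby("tissue")
    }


def sharing_probability(
    records: pd.DataFrame,
    source_set: tuple[str, ...] | list[str],
    target: str,
    n_unique: int = 3000,
    n_resamples: int = 100,
    seed: int = 0,
) -> SharingEstimate:
    """P(VDJ observed in target | observed in every tissue of source_set).

    Each resample independently re-downsamples all emulsions of the involved
    tissues to ``n_unique`` unique VDJs; the estimate is the mean fraction
    over resamples, with the SE of the mean taken across resamples.
    """
    source_set = tuple(source_set)
    if target in source_set:
        raise ValueError("target must not be part of source_set")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    tissues = list(source_set) + [target]
    sub = records[records["tissue"].isin(tissues)]
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_resamples):
        ds = downsample_emulsions(sub, n_unique, int(rng.integers(2**31)))
        if ds.empty:
            continue
        pres = _presence_sets(ds)
        if any(t not in pres for t in tissues):
            continue
        in_source = set.intersection(*(pres[t] for t in source_set))
        if not in_source:
            continue
        fracs.append(len(in_source & pres[target]) / len(in_source))
    if not fracs:
        raise ValueError(
            "sharing probability undefined: no resample produced source VDJs "
            f"(source={source_set}, target={target!r})"
        )
    fr = np.asarray(fracs)
    return SharingEstimate(
        source_set=source_set,
        target=target,
        raw=float(fr.mean()),
        raw_se=float(fr.std(ddof=1) / np.sqrt(len(fr))) if len(fr) > 1 else 0.0,
        n_resamples=len(fr),
        n_unique=n_unique,
    )


def normalize_sharing(
    raw: SharingEstimate,
    records: pd.DataFrame,
    seed: int = 0,
    denom_tissue: str | None = None,
) -> SharingEstimate:
    """Divide raw sharing by the same-tissue replicate re-encounter rate.

    The denominator is the probability that a VDJ present in one downsampled
    emulsion of the source tissue appears in an independent emulsion of the
    same tissue, averaged over all ordered emulsion pairs and the same number
    of resamples.  This conditions on expansion/detectability in the source
    tissue; a tissue shared as often as a replicate of itself normalizes
    to 1.
    """
    if denom_tissue is None:
        if len(raw.source_set) != 1:
            raise ValueError(
                "denom_tissue must be given when source_set has several tissues"
            )
        denom_tissue = raw.source_set[0]
    sub = records[records["tissue"] == denom_tissue]
    if sub.empty:
        raise ValueError(f"no records for denominator tissue {denom_tissue!r}")
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(raw.n_resamples):
        ds = downsample_emulsions(sub, raw.n_unique, int(rng.integers(2**31)))
        if ds.empty:
            continue
        emuls = sorted(ds["emulsion_id"].unique())
        if len(emuls) < 2:
            raise ValueError(
                f"tissue {denom_tissue!r} needs >= 2 emulsions with "
                f">= {raw.n_unique} unique VDJs for replicate normalization"
            )
        sets = {
            e: set(ds.loc[ds["emulsion_id"] == e, "vdj_key"].unique())
            for e in emuls
        }
        pair_fracs = [
            len(sets[i] & sets[j]) / len(sets[i])
            for i in emuls
            for j in emuls
            if i != j and sets[i]
        ]
        if pair_fracs:
            fracs.append(float(np.mean(pair_fracs)))
    if not fracs:
        raise ValueError(f"no replicate emulsion pairs for {denom_tissue!r}")
    den = np.asarray(fracs)
    denominator = float(den.mean())
    if denominator == 0:
        raise ValueError("zero replicate re-encounter probability")
    return SharingEstimate(
        source_set=raw.source_set,
        target=raw.target,
        raw=raw.raw,
        raw_se=raw.raw_se,
        n_resamples=raw.n_resamples,
        n_unique=raw.n_unique,
        denominator=denominator,
        denominator_se=float(den.std(ddof=1) / np.sqrt(len(den)))
        if len(den) > 1
        else 0.0,
        normalized=raw.raw / denominator,
        extras={"denom_tissue": denom_tissue},
    )
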