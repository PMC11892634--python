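"""Within-lineage relative hypermutation statistics and permutation nulls.

A sequence's relative hypermutation level is its rank within its lineage,
scaled to [0, 1] (0 = least, 1 = most hypermutated unique VDJ).  Whether a
label (tissue, cell type) assorts with maturation inside lineages is tested
by comparing the label's CDF of relative levels against bands obtained by
permuting labels among hypermutated VDJs within each lineage — the analysis
that separates lineage-level from cell-level correlates of hypermutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NullBand",
    "relative_levels",
    "permutation_band",
    "measured_cdf",
    "cdf_difference",
    "stratify_by_naive",
]


@dataclass
class NullBand:
    """Pointwise CDF envelope of a label under within-lineage permutation."""

    label: str
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    center: np.ndarray  # pointwise permutation mean
    n_permutations: int
    n_items: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("band bounds inverted")


def relative_levels(
    records: pd.DataFrame,
    label_dim: str = "tissue",
    min_unique: int = 5,
) -> pd.DataFrame:
    """Relative hypermutation level per (unique VDJ, label) within lineages.

    Only hypermutated VDJs (m >= 1) participate; lineages with fewer than
    ``min_unique`` such VDJs are excluded.  rel = (midrank - 1)/(K - 1) over
    the lineage's K participating VDJs ranked by m, ties sharing a midrank.
    A VDJ observed under several label values (e.g. two tissues) contributes
    one row per value; permutations later shuffle labels over these rows.

    Returns columns [lineage_id, vdj_key, m, rel, label]; the number of
    degenerate lineages (all m identical, rel = 0.5) is reported in
    ``result.attrs["n_degenerate_lineages"]``.
    """
    if min_unique < 2:
        raise ValueError("min_unique must be >= 2")
    if "lineage_id" not in records.columns:
        raise ValueError("records need a lineage_id column")
    hyp = records[records["m"] >= 1]
    vdjs = hyp.drop_duplicates("vdj_key")[["lineage_id", "vdj_key", "m"]]
    sizes = vdjs.groupby("lineage_id")["vdj_key"].transform("size")
    vdjs = vdjs[sizes >= min_unique].copy()
    if len(vdjs) == 0:
        out = pd.DataFrame(columns=["lineage_id", "vdj_key", "m", "rel", "label"])
        out.attrs["n_degenerate_lineages"] = 0
        return out

    def _rel(g: pd.Series) -> pd.Series:
        k = len(g)
        return pd.Series((rankdata(g, method="average") - 1) / (k - 1), index=g.index)

    vdjs["rel"] = vdjs.groupby("lineage_id")["m"].transform(_rel)
    n_degenerate = int(
        (vdjs.groupby("lineage_id")["m"].nunique() == 1).sum()
    )

    labels = hyp.drop_duplicates(["vdj_key", label_dim])[
        ["vdj_key", label_dim]
    ].rename(columns={label_dim: "label"})
    out = vdjs.merge(labels, on="vdj_key", how="inner")
    out = out.sort_values(["lineage_id", "vdj_key", "label"]).reset_index(drop=True)
    out.attrs["n_degenerate_lineages"] = n_degenerate
    return out


def _cdf(sorted_values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if sorted_values.size == 0:
        return np.full(grid.size, np.nan)
    return np.searchsorted(sorted_values, grid, side="right") / sorted_values.size


def measured_cdf(rel_records: pd.DataFrame, label: str, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF of rel for one label value, evaluated on ``grid``."""
    vals = np.sort(rel_records.loc[rel_records["label"] == label, "rel"].to_numpy())
    return _cdf(vals, grid)


def permutation_band(
    rel_records: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, NullBand]:
    """Null CDF bands from within-lineage label permutations.

    Each permutation shuffles labels among the participating rows of every
    lineage independently; for each label value, the pointwise min/max CDF
    over permutations forms the band and the pointwise mean the null center.
    The grid is the sorted set of distinct observed rel values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(rel_records) == 0:
        warnings.warn("no records; returning empty band set")
        return {}
    rng = np.random.default_rng(seed)
    df = rel_records.sort_values("lineage_id", kind="stable").reset_index(drop=True)
    lin = df["lineage_id"].to_numpy()
    rel = df["rel"].to_numpy()
    labels = df["label"].to_numpy()
    grid = np.unique(rel)
    label_values = sorted(pd.unique(labels))
    n = len(df)

    sums = {v: np.zeros(grid.size) for v in label_values}
    lo = {v: np.full(grid.size, np.inf) for v in label_values}
    hi = {v: np.full(grid.size, -np.inf) for v in label_values}
    for _ in range(n_perm):
        order = np.lexsort((rng.random(n), lin))
        perm_labels = labels[order]  # rows are lineage-contiguous
        for v in label_values:
            cdf = _cdf(np.sort(rel[perm_labels == v]), grid)
            sums[v] += cdf
            np.minimum(lo[v], cdf, out=lo[v])
            np.maximum(hi[v], cdf, out=hi[v])

    bands = {}
    for v in label_values:
        n_items = int((labels == v).sum())
        bands[v] = NullBand(
            label=v,
            grid=grid,
            lower=lo[v],
            upper=hi[v],
            center=sums[v] / n_perm,
            n_permutations=n_perm,
            n_items=n_items,
        )
    return bands


def cdf_difference(
    rel_records: pd.DataFrame, band: NullBand, label_value: str
) -> pd.DataFrame:
    """Measured minus null-center CDF, with the band re-expressed around 0.

    Returns columns [rel, diff, band_lower, band_upper, inside].
    """
    if band.label != label_value:
        raise ValueError(
            f"band was computed for label {band.label!r}, not {label_value!r}"
        )
    have = np.unique(rel_records["rel"])
    if have.size != band.grid.size or not np.allclose(have, band.grid):
        raise ValueError("rel grid of records does not match the band's grid")
    measured = measured_cdf(rel_records, label_value, band.grid)
    diff = measured - band.center
    lower = band.lower - band.center
    upper = band.upper - band.center
    inside = (measured >= band.lower - 1e-12) & (measured <= band.upper + 1e-12)
    return pd.DataFrame(
        {
            "rel": band.grid,
            "diff": diff,
            "band_lower": lower,
            "band_upper": upper,
            "inside": inside,
        }
    )


def stratify_by_naive(records: pd.DataFrame) -> dict:
    """Split lineages by presence of an unhypermutated naive member.

    Naive B cells turn over within weeks, so lineages still containing one
    are on average recently founded ("young").  Reports, per stratum, the
    hypermutation distribution of memory-cell unique VDJs and the ASC-3
    fraction of cells.
    """
    if "lineage_id" not in records.columns:
        raise ValueError("records need a lineage_id column")
    naive_mask = (records["cell_type"] == "Naive") & (records["m"] == 0)
    naive_lineages = set(records.loc[naive_mask, "lineage_id"].unique())
    if not naive_lineages:
        warnings.warn("no naive cells found; the naive-containing stratum is empty")
    all_lineages = set(records["lineage_id"].unique())

    def summarize(lineage_ids: set) -> dict:
        sub = records[records["lineage_id"].isin(lineage_ids)]
        mem = sub[(sub["cell_type"] == "Memory") & (sub["m"] >= 1)].drop_duplicates(
            "vdj_key"
        )
        diff = sub[sub["cell_type"] != "Naive"]
        return {
            "n_lineages": len(lineage_ids),
            "memory_m": mem["m"].to_numpy(),
            "memory_m_median": float(mem["m"].median()) if len(mem) else np.nan,
            "asc3_fraction": float((diff["cell_type"] == "ASC-3").mean())
            if len(diff)
            else np.nan,
        }

    return {
        "naive_containing": summarize(naive_lineages),
        "naive_free": summarize(all_lineages - naive_lineages),
    }
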