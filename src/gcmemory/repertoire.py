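"""Repertoire ingestion, unique-VDJ collapse, lineage assignment, downsampling.

Cells are read from an AIRR Rearrangement TSV joined to a cell-metadata TSV.
Unique VDJs (identical full heavy-chain nucleotide sequences within a donor)
are the counting unit of most analyses; lineages group unique VDJs descended
from one recombination event via the standard V gene / J gene / junction
clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "read_inputs",
    "collapse_unique_vdjs",
    "assign_lineages",
    "downsample_emulsions",
    "attach_lineages",
    "lineage_tissue_sizes",
]

AIRR_COLUMNS = [
    "sequence_id",
    "cell_id",
    "v_call",
    "j_call",
    "junction",
    "sequence",
    "v_mutation_count",
]
META_COLUMNS = ["cell_id", "donor", "tissue", "emulsion_id", "cell_type"]

_VALID_NT = set("ACGTN")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {missing}")


def read_inputs(airr_path: str, meta_path: str) -> pd.DataFrame:
    """Join an AIRR rearrangement TSV with cell metadata into cell records.

    Cells present on only one side are dropped (tallied in
    ``result.attrs["n_dropped"]``); rows whose junction contains characters
    outside ACGTN or whose mutation count is negative are rejected with a
    warning.  The unique-VDJ key is the donor-scoped full nucleotide
    sequence; V/J calls are truncated to gene level (allele suffix removed).
    """
    airr = pd.read_csv(airr_path, sep="\t", dtype={"junction": str, "sequence": str})
    meta = pd.read_csv(meta_path, sep="\t")
    _require_columns(airr, AIRR_COLUMNS, "AIRR table")
    _require_columns(meta, META_COLUMNS, "metadata table")
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].head(3).tolist()
        raise ValueError(f"duplicate cell_id in metadata, e.g. {dups}")
    if airr["cell_id"].duplicated().any():
        dups = airr.loc[airr["cell_id"].duplicated(), "cell_id"].head(3).tolist()
        raise ValueError(f"duplicate cell_id in AIRR table, e.g. {dups}")

    rec = airr.merge(meta, on="cell_id", how="inner")
    n_dropped = len(airr) + len(meta) - 2 * len(rec)

    bad_junction = ~rec["junction"].fillna("").map(
        lambda s: len(s) > 0 and set(s) <= _VALID_NT
    )
    bad_m = pd.to_numeric(rec["v_mutation_count"], errors="coerce").isna() | (
        pd.to_numeric(rec["v_mutation_count"], errors="coerce") < 0
    )
    n_rejected = int((bad_junction | bad_m).sum())
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} record(s) with malformed junction or "
            "mutation count"
        )
    rec = rec[~(bad_junction | bad_m)].copy()

    rec["m"] = rec["v_mutation_count"].astype(int)
    rec["v_gene"] = rec["v_call"].astype(str).str.split("*").str[0]
    rec["j_gene"] = rec["j_call"].astype(str).str.split("*").str[0]
    rec["junction_nt"] = rec["junction"]
    if "isotype" not in rec.columns:
        rec["isotype"] = "Unknown"
    rec["cell_type"] = rec["cell_type"].fillna("Unknown")
    rec["vdj_key"] = pd.factorize(
        rec["donor"].astype(str) + "\x00" + rec["sequence"].astype(str)
    )[0]
    out = rec[
        [
            "cell_id",
            "donor",
            "tissue",
            "emulsion_id",
            "cell_type",
            "isotype",
            "vdj_key",
            "v_gene",
            "j_gene",
            "junction_nt",
            "sequence",
            "m",
        ]
    ].reset_index(drop=True)
    out.attrs["n_dropped"] = int(n_dropped)
    out.attrs["n_rejected"] = n_rejected
    return out


def collapse_unique_vdjs(records: pd.DataFrame) -> pd.DataFrame:
    """One row per donor-scoped unique VDJ, with cell tallies.

    Raises if cells sharing a vdj_key disagree on their mutation count (a
    violated invariant, since the key identifies one nucleotide sequence).
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    key = ["donor", "vdj_key"] if "donor" in records.columns else ["vdj_key"]
    g = records.groupby(key, sort=True)
    if (g["m"].nunique() > 1).any():
        bad = g["m"].nunique()
        bad = bad[bad > 1].index[:3].tolist()
        raise ValueError(f"conflicting m for identical vdj_key(s): {bad}")
    vdjs = g.agg(
        m=("m", "first"),
        n_cells=("cell_id", "size"),
        n_tissues=("tissue", "nunique"),
    )
    for col in ("v_gene", "j_gene", "junction_nt"):
        if col in records.columns:
            vdjs[col] = g[col].first()
    if "true_lineage_id" in records.columns:
        vdjs["true_lineage_id"] = g["true_lineage_id"].first()
    return vdjs.reset_index()


def _identity_components(junctions: list[str], threshold: float) -> np.ndarray:
    """Single-linkage components under junction identity >= threshold.

    All junctions share one length (callers group by length first), so
    identity is the fraction of matching positions.
    """
    n = len(junctions)
    if n == 1:
        return np.zeros(1, dtype=int)
    mat = np.frombuffer("".join(junctions).encode("ascii"), dtype=np.uint8).reshape(
        n, -1
    )
    length = mat.shape[1]
    max_mismatch = int(np.floor((1.0 - threshold) * length + 1e-9))
    rows, cols = [], []
    step = max(1, int(2**22 // max(n * length, 1)))
    for start in range(0, n, step):
        block = mat[start : start + step]
        mism = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
        r, c = np.nonzero(mism <= max_mismatch)
        rows.append(r + start)
        cols.append(c)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = csr_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def assign_lineages(
    vdjs: pd.DataFrame, identity_threshold: float = 0.85, seed: int = 0
) -> pd.Series:
    """Partition unique VDJs into lineages.

    Candidate groups share (donor,) V gene, J gene and junction length;
    within a group, single-linkage clustering on junction nucleotide identity
    at ``identity_threshold`` defines lineages.  The partition is a function
    of the set of sequences only: groups are processed in sorted key order
    and junctions sorted lexicographically, so input order is irrelevant.
    Returns an integer lineage_id aligned with ``vdjs``.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if len(vdjs) == 0:
        raise ValueError("no unique VDJs to cluster")
    if vdjs["junction_nt"].isna().any() or (vdjs["junction_nt"] == "").any():
        raise ValueError("every unique VDJ needs a nonempty junction")

    df = vdjs.reset_index(drop=True)
    key_cols = ["v_gene", "j_gene"]
    if "donor" in df.columns:
        key_cols = ["donor"] + key_cols
    jlen = df["junction_nt"].str.len()
    lineage = np.full(len(df), -1, dtype=np.int64)
    next_id = 0
    groups = df.groupby(key_cols + [jlen.rename("jlen")], sort=True).indices
    for key in sorted(groups):
        idx = np.asarray(groups[key])
        juncs = df.loc[idx, "junction_nt"]
        order = np.argsort(juncs.to_numpy())
        idx = idx[order]
        labels = _identity_components(
            juncs.to_numpy()[order].tolist(), identity_threshold
        )
        # relabel components by first occurrence for deterministic ids
        _, first_pos = np.unique(labels, return_index=True)
        rank = {labels[p]: k for k, p in enumerate(sorted(first_pos))}
        lineage[idx] = np.array([rank[l] for l in labels]) + next_id
        next_id += len(rank)
    return pd.Series(lineage, index=vdjs.index, name="lineage_id")


def attach_lineages(
    records: pd.DataFrame, identity_threshold: float = 0.85, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse records to unique VDJs, cluster lineages, map back to cells.

    Returns ``(records + lineage_id column, vdjs + lineage_id column)``.
    """
    vdjs = collapse_unique_vdjs(records)
    vdjs["lineage_id"] = assign_lineages(vdjs, identity_threshold, seed)
    key = ["donor", "vdj_key"] if "donor" in records.columns else ["vdj_key"]
    out = records.merge(vdjs[key + ["lineage_id"]], on=key, how="left")
    out.attrs.update(records.attrs)
    return out, vdjs


def downsample_emulsions(
    records: pd.DataFrame, n_unique: int, seed: int
) -> pd.DataFrame:
    """Downsample every emulsion to the same number of unique VDJs.

    Per emulsion, ``n_unique`` of its unique VDJs are drawn uniformly and all
    their cells kept; emulsions with fewer unique VDJs are dropped entirely.
    This equalizes sampling depth before cross-tissue comparisons.
    """
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    rng = np.random.default_rng(seed)
    kept = []
    for emulsion in sorted(records["emulsion_id"].unique()):
        sub = records[records["emulsion_id"] == emulsion]
        uniq = np.sort(sub["vdj_key"].unique())
        if uniq.size < n_unique:
            continue
        chosen = rng.choice(uniq, size=n_unique, replace=False)
        kept.append(sub[sub["vdj_key"].isin(chosen)])
    if not kept:
        return records.iloc[0:0].copy()
    out = pd.concat(kept, ignore_index=True)
    out.attrs.update(records.attrs)
    return out


def lineage_tissue_sizes(records: pd.DataFrame) -> pd.DataFrame:
    """Per (lineage, tissue): unique-VDJ count and repertoire fraction x.

    x is the fraction of the tissue's unique VDJs attributable to the
    lineage; within a tissue, x sums to 1 over the lineages present.
    """
    if "lineage_id" not in records.columns:
        raise ValueError("records need a lineage_id column (see attach_lineages)")
    uniq = records.drop_duplicates(["tissue", "vdj_key"])
    counts = (
        uniq.groupby(["lineage_id", "tissue"], sort=True)
        .size()
        .rename("n_unique")
        .reset_index()
    )
    totals = counts.groupby("tissue")["n_unique"].transform("sum")
    counts["x"] = counts["n_unique"] / totals
    return counts
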