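"""Configuration, orchestration and reporting for full pipeline runs.

A run is driven by one YAML config carrying the simulator parameter blocks
and every analysis threshold.  A single seed fans out deterministically to
per-stage seeds, so stages can be re-run in isolation and a re-run with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gc_model as gm
from . import lineage_stats as ls
from . import tissue_sharing as tsh
from .params import BurstParams, GCParams, LocalizationParams, SamplingParams
from .repertoire import attach_lineages, read_inputs
from .simulate import sample_repertoire, simulate_truth, write_truth

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_report"]

log = logging.getLogger("gcmemory")

#: Stage indices for seed derivation; fixed so stages are re-runnable alone.
_STAGES = {
    "simulate": 1,
    "sample": 2,
    "lineages": 3,
    "lineage_stats": 4,
    "gc_model": 5,
    "sharing": 6,
}


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed below 2**31, stable across runs."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisThresholds:
    """Analysis defaults, each anchored to the study's headline settings."""

    junction_identity: float = 0.85
    downsample_unique: int = 5000  # discovery-curve depth per emulsion
    sharing_unique: int = 3000  # clone-sharing depth per emulsion
    n_perm: int = 100
    n_resamples: int = 100
    min_unique_rel: int = 5  # lineage size floor for relative-HM analysis
    min_unique_comp: int = 2  # lineage size floor for composition null
    m_stab: int = 10
    min_bin_cells: int = 10
    min_cells: int = 6
    min_lineages: int = 10
    v_length: int = 300  # templated V length: m=10 is ~3% divergence


@dataclass
class RunConfig:
    seed: int
    donor: str = "sim1"
    n_lineages: int = 2000
    founders_per_lineage: int = 10
    naive_fraction: float = 0.25
    gc: GCParams = field(default_factory=GCParams)
    localization: LocalizationParams = field(default_factory=LocalizationParams)
    burst: BurstParams = field(default_factory=BurstParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["gc"]["exit_rates"] = dict(self.gc.exit_rates)
        loc = d["localization"]
        loc["tissues"] = list(self.localization.tissues)
        loc["leak_prob"] = (
            {f"{a}->{b}": p for (a, b), p in self.localization.leak_map().items()}
            if not isinstance(self.localization.leak_prob, (int, float))
            else self.localization.leak_prob
        )
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("config must set a seed")
        kwargs: dict[str, Any] = {}
        for key in ("seed", "donor", "n_lineages", "founders_per_lineage", "naive_fraction"):
            if key in d:
                kwargs[key] = d[key]
        if "gc" in d:
            kwargs["gc"] = GCParams(**d["gc"])
        if "localization" in d:
            loc = dict(d["localization"])
            if isinstance(loc.get("leak_prob"), dict):
                loc["leak_prob"] = {
                    tuple(k.split("->")): v for k, v in loc["leak_prob"].items()
                }
            if "tissues" in loc:
                loc["tissues"] = tuple(loc["tissues"])
            if "home_weights" in loc and loc["home_weights"] is not None:
                loc["home_weights"] = tuple(loc["home_weights"])
            kwargs["localization"] = LocalizationParams(**loc)
        if "burst" in d:
            kwargs["burst"] = BurstParams(**d["burst"])
        if "sampling" in d:
            kwargs["sampling"] = SamplingParams(**d["sampling"])
        if "thresholds" in d:
            defaults = AnalysisThresholds()
            for k, v in d["thresholds"].items():
                if getattr(defaults, k) != v:
                    log.info("threshold override: %s = %r", k, v)
            kwargs["thresholds"] = AnalysisThresholds(**d["thresholds"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_simulate(config: RunConfig, outdir: str) -> str:
    """Simulate truth, sample a repertoire, write the dataset directory."""
    os.makedirs(outdir, exist_ok=True)
    log.info("simulate: %d lineages, seed %d", config.n_lineages, config.seed)
    res = simulate_truth(
        config.gc,
        config.localization,
        config.burst,
        config.n_lineages,
        config.founders_per_lineage,
        config.naive_fraction,
        derive_seed(config.seed, "simulate"),
        v_length=config.thresholds.v_length,
    )
    records = sample_repertoire(
        res.cells, config.donor, config.sampling, derive_seed(config.seed, "sample")
    )
    write_truth(records, outdir, res.lineages)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest = {
        "config_hash": config.config_hash(),
        "n_cells": int(len(records)),
        "attrition": res.attrition,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("simulate: wrote %d cell records to %s", len(records), outdir)
    return outdir


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("lineage_stats")
def _analyze_lineage_stats(records, th, seed, outdir, summary):
    for dim, fname in (("tissue", "relhm_tissue.tsv"), ("cell_type", "relhm_celltype.tsv")):
        rel = ls.relative_levels(records, dim, th.min_unique_rel)
        if len(rel) == 0:
            log.warning("no lineages pass min_unique for %s", dim)
            continue
        bands = ls.permutation_band(rel, th.n_perm, seed)
        frames = []
        for label, band in bands.items():
            diff = ls.cdf_difference(rel, band, label)
            diff.insert(0, "label", label)
            frames.append(diff)
        pd.concat(frames, ignore_index=True).to_csv(
            os.path.join(outdir, fname), sep="\t", index=False
        )
    strata = ls.stratify_by_naive(records)
    summary["naive_strata"] = {
        k: {
            "n_lineages": v["n_lineages"],
            "memory_m_median": v["memory_m_median"],
            "asc3_fraction": v["asc3_fraction"],
        }
        for k, v in strata.items()
    }


@_stage("gc_model")
def _analyze_gc_model(records, th, outdir, summary):
    members = gm.differentiated_members(records, min_m=1, unit="vdj")
    hazards = gm.exit_hazard(members, min_bin_cells=th.min_bin_cells)
    plateaus = gm.plateau_rates(hazards, th.m_stab)
    curves, spread = gm.scaled_hazard(hazards, plateaus)
    rows = []
    for t, h in hazards.items():
        df = pd.DataFrame(
            {
                "cell_type": t,
                "m": h.m,
                "lambda_hat": h.lambda_hat,
                "se": h.se,
                "counts": h.counts,
                "at_risk": h.at_risk,
                "masked": h.masked,
                "scaled": curves[t]["scaled"],
            }
        )
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(
        os.path.join(outdir, "hazard.tsv"), sep="\t", index=False
    )
    pooled = gm.differentiated_members(records, min_m=1, unit="vdj", pool_asc=True)
    pooled_plat = gm.plateau_rates(
        gm.exit_hazard(pooled, min_bin_cells=th.min_bin_cells), th.m_stab
    )
    summary["plateau"] = {
        "rates": plateaus.rates,
        "ratios": plateaus.ratios,
        "memory_over_asc": pooled_plat.ratio("Memory", "ASC")
        if {"Memory", "ASC"} <= set(pooled_plat.rates)
        else None,
        "m_stab": th.m_stab,
    }
    summary["fraction_mature_exits"] = gm.fraction_mature_exits(
        gm.differentiated_members(records, min_m=0, unit="vdj"), th.m_stab
    )

    mix = gm.type_mixture(members, smoothing_window=3)
    model = gm.model_mixture(plateaus, mix.m, mix.types)
    mix_rows = []
    for k, t in enumerate(mix.types):
        mix_rows.append(
            pd.DataFrame(
                {
                    "cell_type": t,
                    "m": mix.m,
                    "p_empirical": mix.probs[:, k],
                    "p_model": model.probs[:, k],
                }
            )
        )
    pd.concat(mix_rows, ignore_index=True).to_csv(
        os.path.join(outdir, "mixture.tsv"), sep="\t", index=False
    )

    cells = gm.differentiated_members(records, min_m=1, unit="cell")
    cmix = gm.type_mixture(cells, smoothing_window=3)
    null = gm.lineage_composition_null(
        cells, cmix, th.min_unique_comp, th.min_cells, th.min_lineages
    )
    null.by_size.to_csv(
        os.path.join(outdir, "composition_by_size.tsv"), sep="\t", index=False
    )
    gm.composition_zscores(null).to_csv(
        os.path.join(outdir, "composition_z.tsv"), sep="\t", index=False
    )
    summary["composition_z"] = {
        r["cell_type"]: r["z"]
        for _, r in gm.composition_zscores(null).iterrows()
    }


@_stage("sharing")
def _analyze_sharing(records, th, seed, outdir, summary):
    tissues = sorted(records["tissue"].unique())
    if len(tissues) >= 2:
        tsh.privacy_fractions(records, th.n_perm, seed).to_csv(
            os.path.join(outdir, "privacy.tsv"), sep="\t", index=False
        )
    hist, expanded = tsh.clone_size_distribution(records)
    hist.to_csv(os.path.join(outdir, "clone_sizes.tsv"), sep="\t", index=False)
    summary["expanded_vdj_fraction"] = expanded

    xc_fits, sharing_rows = {}, []
    for a in tissues:
        for b in tissues:
            if a == b:
                continue
            try:
                pts = tsh.discovery_curve(
                    records, a, b, th.downsample_unique, seed
                )
                fit = tsh.fit_xc(pts)
                pts.to_csv(
                    os.path.join(outdir, f"discovery_{a}_{b}.tsv"),
                    sep="\t",
                    index=False,
                )
                xc_fits[f"{a}->{b}"] = {
                    "x_c": fit.x_c,
                    "ci": list(fit.ci),
                    "n_points": fit.n_points,
                }
            except ValueError as exc:
                log.warning("discovery %s->%s skipped: %s", a, b, exc)
            try:
                raw = tsh.sharing_probability(
                    records, (a,), b, th.sharing_unique, th.n_resamples, seed
                )
                est = tsh.normalize_sharing(raw, records, seed)
                sharing_rows.append(
                    {
                        "source": a,
                        "target": b,
                        "raw": est.raw,
                        "raw_se": est.raw_se,
                        "denominator": est.denominator,
                        "normalized": est.normalized,
                    }
                )
            except ValueError as exc:
                log.warning("sharing %s->%s skipped: %s", a, b, exc)
    if sharing_rows:
        pd.DataFrame(sharing_rows).to_csv(
            os.path.join(outdir, "sharing.tsv"), sep="\t", index=False
        )
    summary["x_c"] = xc_fits
    summary["sharing"] = sharing_rows


def run_analyze(config: RunConfig, dataset: str, outdir: str) -> str:
    """Run lineage assignment and all analysis stages over a dataset."""
    os.makedirs(outdir, exist_ok=True)
    th = config.thresholds
    summary: dict[str, Any] = {"config_hash": config.config_hash()}

    records = read_inputs(
        os.path.join(dataset, "airr.tsv"), os.path.join(dataset, "meta.tsv")
    )
    try:
        records, vdjs = attach_lineages(records, th.junction_identity)
    except Exception as exc:
        raise RuntimeError(f"stage 'lineages' failed: {exc}") from exc
    vdjs[["vdj_key", "lineage_id", "m", "v_gene", "j_gene"]].to_csv(
        os.path.join(outdir, "lineage_assignments.tsv"), sep="\t", index=False
    )
    summary["n_records"] = int(len(records))
    summary["n_unique_vdjs"] = int(len(vdjs))
    summary["n_lineages"] = int(vdjs["lineage_id"].nunique())

    truth_path = os.path.join(dataset, "truth_cells.tsv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, sep="\t")
        j = records.merge(
            truth[["cell_id", "true_lineage_id"]], on="cell_id", how="inner"
        ).drop_duplicates("vdj_key")
        both = j.dropna(subset=["lineage_id", "true_lineage_id"])
        summary["lineage_recovery"] = {
            "n_vdjs": int(len(both)),
            "ari": _adjusted_rand(
                both["true_lineage_id"].to_numpy(), both["lineage_id"].to_numpy()
            ),
        }

    _analyze_lineage_stats(
        records, th, derive_seed(config.seed, "lineage_stats"), outdir, summary
    )
    _analyze_gc_model(records, th, outdir, summary)
    _analyze_sharing(
        records, th, derive_seed(config.seed, "sharing"), outdir, summary
    )

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    log.info("analyze: wrote results to %s", outdir)
    return outdir


def _adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two labelings (contingency form)."""
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(tab).sum()
    sum_a = comb(tab.sum(axis=1)).sum()
    sum_b = comb(tab.sum(axis=0)).sum()
    n = comb(tab.sum())
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


_REPORT_SECTIONS = [
    ("Tissue privacy of lineages", "privacy.tsv"),
    ("Cross-tissue discovery and critical size", "summary.json:x_c"),
    ("Within-lineage hypermutation by tissue", "relhm_tissue.tsv"),
    ("Within-lineage hypermutation by cell type", "relhm_celltype.tsv"),
    ("Scaled effective exit rates", "hazard.tsv"),
    ("Type mixture vs constant-rate model", "mixture.tsv"),
    ("Lineage type content vs independence null", "composition_z.tsv"),
    ("Type fractions by lineage size", "composition_by_size.tsv"),
    ("Clone size distributions", "clone_sizes.tsv"),
    ("Raw cross-tissue sharing", "sharing.tsv"),
    ("Replicate-normalized sharing", "sharing.tsv:normalized"),
]


def run_report(results: str, out_path: str | None = None) -> str:
    """Render a human-readable markdown report from a results directory."""
    out_path = out_path or os.path.join(results, "report.md")
    summary = {}
    spath = os.path.join(results, "summary.json")
    if os.path.exists(spath):
        with open(spath) as fh:
            summary = json.load(fh)
    lines = ["# Repertoire memory-formation report", ""]
    lines.append(f"Config hash: {summary.get('config_hash', 'n/a')}")
    lines.append("")
    n_present = 0
    for title, source in _REPORT_SECTIONS:
        fname = source.split(":")[0]
        path = os.path.join(results, fname)
        lines.append(f"## {title}")
        if fname == "summary.json":
            key = source.split(":")[1]
            if key in summary and summary[key]:
                n_present += 1
                lines.append("```json")
                lines.append(json.dumps(summary[key], indent=1, default=float))
                lines.append("```")
            else:
                lines.append("_Section skipped: no output available._")
        elif os.path.exists(path):
            n_present += 1
            df = pd.read_csv(path, sep="\t")
            lines.append(df.head(25).to_markdown(index=False))
            if len(df) > 25:
                lines.append(f"_... {len(df) - 25} further rows omitted._")
        else:
            lines.append(f"_Section skipped: {fname} not found._")
        lines.append("")
    for key in ("plateau", "fraction_mature_exits", "expanded_vdj_fraction", "lineage_recovery"):
        if key in summary:
            lines.append(f"- **{key}**: {json.dumps(summary[key], default=float)}")
    lines.append("")
    lines.append(f"_{n_present} of {len(_REPORT_SECTIONS)} sections rendered._")
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines))
    return out_path
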