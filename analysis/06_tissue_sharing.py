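#!/usr/bin/env python
"""Tissue privacy, dispersal critical sizes, clone sizes, clone sharing.

Lineages are strongly tissue-private; the probability of discovering a
lineage in a second tissue grows with its size as 1 - exp(-x/x_c); and
expanded clones (ASC-3 bursts) are shared across tissues with high
replicate-normalized probability.
"""

import json
import pathlib

import pandas as pd

from gcmemory import tissue_sharing as tsh
from gcmemory.pipeline import RunConfig
from gcmemory.repertoire import attach_lineages, read_inputs

HERE = pathlib.Path(__file__).parent
DS = HERE.parent / "results" / "dataset"
OUT = HERE.parent / "results" / "sharing"
OUT.mkdir(parents=True, exist_ok=True)

cfg = RunConfig.from_yaml(str(HERE / "config.yaml"))
th = cfg.thresholds

records = read_inputs(str(DS / "airr.tsv"), str(DS / "meta.tsv"))
records, _ = attach_lineages(records)

privacy = tsh.privacy_fractions(records, n_perm=th.n_perm, seed=31)
privacy.to_csv(OUT / "privacy.tsv", sep="\t", index=False)
print(privacy.round(3).to_string(index=False))

hist, expanded = tsh.clone_size_distribution(records)
hist.to_csv(OUT / "clone_sizes.tsv", sep="\t", index=False)
print(f"\nexpanded unique-VDJ fraction (clone size > 1): {expanded:.4f}")

xc = {}
for a, b in [("Spleen", "Blood"), ("Blood", "Spleen"), ("BM", "Blood")]:
    try:
        pts = tsh.discovery_curve(records, a, b, th.downsample_unique, seed=32)
        fit = tsh.fit_xc(pts)
        pts.to_csv(OUT / f"discovery_{a}_{b}.tsv", sep="\t", index=False)
        xc[f"{a}->{b}"] = {"x_c": fit.x_c, "ci": fit.ci, "n": fit.n_points}
        print(f"x_c {a}->{b}: {fit.x_c:.4f} "
              f"(95% CI {fit.ci[0]:.4f}-{fit.ci[1]:.4f}, n={fit.n_points})")
    except ValueError as exc:
        print(f"x_c {a}->{b}: not identifiable ({exc})")

rows = []
for a, b in [("Spleen", "Blood"), ("BM", "Blood"), ("LN", "Blood")]:
    raw = tsh.sharing_probability(records, (a,), b, th.sharing_unique,
                                  th.n_resamples, seed=33)
    est = tsh.normalize_sharing(raw, records, seed=34)
    rows.append({"source": a, "target": b, "raw": est.raw,
                 "denominator": est.denominator, "normalized": est.normalized})
share = pd.DataFrame(rows)
share.to_csv(OUT / "sharing.tsv", sep="\t", index=False)
with open(OUT / "xc.json", "w") as fh:
    json.dump(xc, fh, indent=1, default=list)
print("\n" + share.round(4).to_string(index=False))
print("\nRaw sharing is limited by sampling depth; normalizing by the "
      "replicate re-encounter rate shows expanded clones are broadly shared.")
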