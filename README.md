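# gcmemory

Quantitative analysis of how long-term B cell memory forms, inferred from
multi-tissue B cell receptor (BCR) repertoires — with a ground-truthed
synthetic repertoire generator so every inference stage can be validated by
parameter recovery.

## The scientific problem

When, during affinity maturation, are memory B cells and antibody-secreting
cells (ASCs) created, and how do related cells distribute across tissues?
Long-lived ASCs live mainly in the bone marrow, which is rarely sampled, so
the dynamics must be read out statistically from a single snapshot: the
genetic relationships (shared VDJ recombinations) and hypermutation counts
of B cells sampled across immune-rich tissues.  This package implements
that read-out for repertoires of heavy-chain VDJs with per-cell tissue,
cell-type and hypermutation annotations, and is aimed at computational
immunologists working with single-cell VDJ data (AIRR Rearrangement TSVs).

## The model

A germinal-center B cell faces, in every cycle, a constant probability of
death (`δ`) or of exiting as differentiated type *t* (`r_t`); survivors
accrue hypermutations (1 per cycle by default, so the hypermutation count
*m* is a molecular clock).  With total event rate `Λ = Σ_t r_t + δ`, the
*m* of exiting cells is geometric: `P(m) = Λ(1−Λ)^m`, identically for every
type — so within a lineage, cell types and tissues are uniformly spread
over relative hypermutation levels even though repertoire-wide averages
differ between lineages (Simpson's paradox).

The main inference tools:

- **Effective exit rates** (`gc_model.exit_hazard`): the hazard
  `λ̂_t(m) = C_t(m) / S(m)`, with `C_t(m)` the unique VDJs of type *t* at
  exactly *m* mutations and `S(m)` those of any differentiated type at
  ≥ *m*.  Dead cells are unobservable, so `λ̂_t` estimates `r_t·Λ/Σr`;
  everything reported is a ratio or plateau-scaled curve, which is
  invariant to that factor.  Above `m_stab = 10` the rates plateau; the
  plateau ratio Memory/ASC is the headline relative rate of memory vs ASC
  creation.
- **Within-lineage permutation nulls** (`lineage_stats`): each unique VDJ's
  relative hypermutation level (rank in its lineage scaled to [0, 1]) is
  compared, per tissue or cell type, against bands from 100 within-lineage
  label permutations.
- **Composition nulls** (`gc_model.lineage_composition_null`): conditioning
  on a lineage's member *m* values and assuming independent fates,
  `P(contains type t) = 1 − Π_i (1 − p_t(m_i))`.
- **Poisson dispersal** (`tissue_sharing.fit_xc`): a lineage occupying
  fraction *x* of one tissue's unique VDJs is found in another with
  probability `1 − e^(−x/x_c)`; `x_c` is fit by Bernoulli maximum
  likelihood with profile-likelihood intervals.
- **Replicate-normalized sharing** (`tissue_sharing.normalize_sharing`):
  cross-tissue VDJ sharing divided by the probability of re-encountering a
  VDJ in an independent emulsion of the same tissue, which conditions on
  expansion and detectability.

The simulator (`gcmemory.simulate`) generates all of this with known truth:
lineage homing with rare per-cell leakage, per-lineage rate multipliers
(optionally coupled to ASC-tilted composition), naive-cell emission, ASC-3
clonal bursts, and emulsion-based subsampling with replicate emulsions.

## Worked example

```python
from gcmemory import GCParams, LocalizationParams, BurstParams, simulate_truth
from gcmemory import gc_model as gm

gc = GCParams(death_rate=0.076)          # total event rate 0.1 per cycle
loc = LocalizationParams(tissues=("BM",))
res = simulate_truth(gc, loc, BurstParams(), n_lineages=1,
                     founders_per_lineage=200_000, naive_fraction=0.0,
                     seed=7, founder_dist="fixed", sequences=False)
cells = res.cells.rename(columns={"clone_id": "vdj_key"})
members = gm.differentiated_members(cells, min_m=1, pool_asc=True)
plateaus = gm.plateau_rates(gm.exit_hazard(members), m_stab=10)
print(f"exits simulated: {members['vdj_key'].nunique()}")
print(f"mean hypermutation count: {cells['m'].mean():.2f}  (model: (1-0.1)/0.1 = 9)")
print(f"plateau exit rates: { {t: round(r, 4) for t, r in plateaus.rates.items()} }")
print(f"Memory/ASC ratio: {plateaus.ratio('Memory', 'ASC'):.3f}  (generative: 1.400)")
```

prints

```
exits simulated: 43431
mean hypermutation count: 9.01  (model: (1-0.1)/0.1 = 9)
plateau exit rates: {'ASC': 0.041, 'Memory': 0.0592}
Memory/ASC ratio: 1.444  (generative: 1.400)
```

200 000 founders at the default rates (Memory 0.014, pooled ASC 0.010,
death 0.076) yield ~43 000 hypermutated exits; the mean hypermutation count
matches the geometric expectation and the plateau-rate ratio recovers the
generative 40% excess of memory over ASC creation to within sampling error.

## Analysis scripts

`analysis/01…07` form a narrated end-to-end study on a baseline synthetic
donor (`analysis/config.yaml`): simulate the dataset, recover lineages
(ARI 1.0 at the default 85% junction-identity threshold), test
within-lineage label assortment, estimate exit rates and type mixtures,
score lineage composition against the independence null, and quantify
tissue privacy, dispersal critical sizes and normalized clone sharing.
Each script writes TSV/JSON tables under `results/` and prints what it
found.  The same pipeline is scriptable via the `gcmemory` CLI
(`simulate`, `analyze`, `report`) from a single YAML config.

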