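# Methods

## The generative model

Affinity maturation is modeled as a discrete-time absorbing Markov chain
per cell.  Each germinal-center cycle, a cell first faces an event draw —
death with probability `δ`, exit as differentiated type *t* with
probability `r_t` — and, if no event occurs, accrues hypermutations
(deterministically 1 per cycle by default).  Because the event precedes
accrual, an exiting cell's hypermutation count *m* equals the number of
completed cycles and is geometric on m = 0, 1, 2, …:

    P(exit of type t at m) = r_t (1 − Λ)^m,      Λ = Σ_t r_t + δ,

so the mean *m* of exits is (1 − Λ)/Λ and the type of an exit is
independent of its *m* (`p_t = r_t/Σr`).  Both properties are exercised
directly by tests (chi-square against the geometric law; constancy of the
type mixture across *m* bins).

Trajectories are non-branching: each founder is an independent single-cell
chain.  This makes the geometric marginal exact.  Whether clonal expansion
*inside* the germinal center reshapes the observable distributions is an
open modeling question; since every downstream statistic conditions on the
set of observed exits rather than on GC population sizes, the non-branching
chain is the minimal model that reproduces the observable structure.  A
Poisson mutation option (`mutation_dist="poisson"`) exists for robustness
checks and is excluded from closed-form tests.

### Low-hypermutation suppression

Below a stabilization threshold `m_stab` (default 10, ≈3% divergence of a
300 nt templated V segment) all exit rates are multiplied by a common
`suppression_factor` f ∈ (0, 1]; death is not suppressed.  This reproduces
an early-maturation regime in which every cell type's effective exit rate
sits below its long-term value by the same multiplicative factor.

A subtlety worth recording: the hazard estimator (below) uses only observed
exits in its risk set, because dead cells are unobservable.  With death
unsuppressed and δ > 0, the *estimated* scaled hazard below `m_stab` is not
exactly f (it interpolates between f and 1, identically for all types —
the equal-multiplicative-factor structure is preserved, the absolute level
is not).  With δ = 0 the estimated scaled hazard equals f exactly, so the
quantitative suppression-recovery benchmark runs at δ = 0; the
equal-factor (cross-type spread) assertion is valid at any δ.

### Lineage heterogeneity and Simpson's paradox

`lineage_rate_dispersion` draws a positive, mean-one, gamma-distributed
multiplier g per lineage applied to the *total* event rate (relative exit
rates preserved, realized per-cycle probability clipped at 1).  Dispersion
alone cannot move repertoire-level mean *m* apart between types: the
lineage multiplier cancels from the per-exit type probability, so each
type's *m*-marginal is the same mixture of geometrics.  Repertoire-level
type differences require lineage-level correlation between maturation
extent and composition.  `maturation_type_coupling` κ supplies it: the
ASC share of a lineage's exit odds is tilted by g^(−κ) (renormalized to
keep Λ fixed), so slow-maturing, highly hypermutated lineages are
ASC-richer while within-lineage type ratios remain constant over cycles.
With dispersion 0.6 and κ = 1 the benchmark dataset shows ASCs ~7
mutations above memory cells at the repertoire level while the
within-lineage permutation band stays clean — the Simpson's-paradox
structure in one fixture.

### Localization, naive cells, bursts, sampling

- Each lineage homes to one tissue (`home_weights`); each exiting cell
  leaks to tissue B with per-cell probability `leak_prob[(home, B)]`.
  This implies the Poisson discovery law: a lineage with n cells in its
  home tissue appears in B with probability 1 − (1 − p)^n ≈ 1 − e^(−x/x_c).
- A `naive_fraction` of lineages emit one unmutated naive clone (mean two
  cells) that never enters the GC; `young_lineage_max_cycles` optionally
  truncates naive-containing lineages at a low cycle count to emulate
  recently founded lineages.
- Burst-prone lineages (probability `burst_lineage_prob`) expand one
  existing member clone into geometric-mean-`burst_size_mean` identical
  ASC-3 cells, optionally spread across all tissues — clonal expansion
  without hypermutation, the driver of cross-tissue clone sharing.
- Sampling partitions cells by tissue into `emulsions_per_tissue` droplet
  emulsions with independent capture (`capture_prob`).  Replicate
  emulsions are what make the empirical sampling-probability normalization
  possible, so ≥ 2 per tissue is required for normalized sharing.
- Founder counts per lineage are geometric with mean
  `founders_per_lineage` (option `fixed`), giving the broad lineage-size
  distribution the discovery-curve analysis needs.

### Sequences

One founder junction (30–60 nt, uniform random) and one founder V segment
(default 300 nt) per lineage.  Clones carry the founder junction with
independent per-site substitutions at 0.02/nt and a V segment with their
annotated *m* substitutions at random positions; clones of a lineage whose
sequences collide (typically unmutated clones) are merged so that "same
sequence ⇒ same clone" holds exactly.  Sequence synthesis is skipped
(`sequences=False`) in large rate-inference simulations where only clone
identities matter.

## Inference choices

- **Lineage assignment**: exact match on (donor, V gene, J gene, junction
  length), then single-linkage clustering at 85% junction identity —
  the field-standard heuristic.  Gene-level (not allele-level) V/J
  matching; the threshold is a config knob.  Validated by recovery:
  adjusted Rand index 1.0 against simulated truth at the default junction
  mutation rate, degrading only above ~0.9 thresholds (over-splitting).
  Single linkage is implemented as connected components of the
  identity ≥ threshold graph, so lowering the threshold can only merge
  clusters (monotonicity is property-tested).
- **Counting units**: hazards and mixtures count unique VDJs (suppressing
  clonal-expansion weighting; a cell-weighted mode exists), while the
  lineage-composition null counts cells, since correlated expansion is
  exactly the signal it tests for.
- **Relative hypermutation**: only hypermutated members (m ≥ 1)
  participate; lineages need ≥ 5 such unique VDJs; ties share midranks
  (rel = (midrank − 1)/(K − 1)); a VDJ observed under several label values
  contributes one item per value and permutations shuffle labels over
  items within lineages.  The null band is the pointwise min/max CDF over
  100 permutations; the null center is the permutation mean (lower
  variance than the median).  The grid is the sorted set of observed rel
  values, with no interpolation.  Coverage calibration: the measured CDF
  and the permutation CDFs are exchangeable, so pointwise exceedance is
  ≤ 2/(n_perm + 1); long correlated excursions outside the envelope still
  occur in a few percent of runs regardless of dataset size, which is the
  statistic's intrinsic run-level false-positive rate.
- **Hazard masking**: bins with fewer than 10 members at that *m* (or an
  empty risk set) are masked; plateau rates are risk-set-weighted means
  over unmasked bins at m ≥ 10, i.e. pooled ΣC_t/ΣS estimates.
- **Type mixture**: centered moving-window smoothing of counts, window 3
  (window ∈ {1, 3, 5} is a one-line sensitivity diagnostic); the
  constant-rate model mixture is p_t = plateau_t/Σplateau, constant in m.
  Members whose *m* falls outside the mixture support map to the nearest
  defined bin and are counted.
- **x_c fitting**: Bernoulli maximum likelihood on unbinned lineage
  points, optimized on log x_c with a bounded scalar minimizer (tolerance
  1e−10); 95% CI by profile likelihood (Δlogℓ = 1.92).  A least-squares
  fit on log-binned means is provided as a diagnostic, and tests pin the
  MLE to a brute-force 10⁴-point likelihood grid to 4 significant figures.
- **Sharing**: presence is evaluated on emulsions downsampled to a common
  unique-VDJ count (smaller emulsions dropped); the raw estimate averages
  whole-dataset re-downsamples, with the SE taken across those resamples
  (replicate 10X runs, when a tissue has them, enter through the
  denominator).  The denominator averages all ordered emulsion pairs of
  the source tissue.  "Expanded" is never thresholded — conditioning on
  detectability is what the normalization does.

## What the generator does and does not emulate

It reproduces the statistical structure the inference depends on: lineages
of related VDJs with geometric per-type hypermutation, lineage-level tissue
homing with rare leakage, lineage-level rate heterogeneity with
composition coupling, correlated ASC-3 bursts, and emulsion subsampling
with replicates.  It does not model selection on affinity, GC population
dynamics, nucleotide-context-biased hypermutation targeting, class-switch
dynamics, transcriptomes, or cross-donor (public) clones.  Passing
recovery tests therefore demonstrates the estimators' correctness under
the stated model, not robustness to real-data artifacts such as sequencing
error, allele miscalls or doublets.

## Problem sizes

Benchmarks are sized for comfortable statistical resolution at interactive
runtimes: the rate-ratio benchmark uses 5×10⁵ founders (~10⁵ hypermutated
exits; ratio SE ≈ 0.016), the hazard-constancy benchmark 10⁶ founders with
δ = 0 (9×10⁵ exits, per-bin scaled SE ≤ 0.025 out to m = 30), geometric
GOF 20 runs × 10⁵ founders, x_c recovery 12 000 lineages per leak value
(≥ 100 expected discoveries at the smallest leak), permutation calibration
20 runs of 600 lineages × mean 60 founders, and composition/normalization
3 000 lineages.  The full acceptance battery completes in a few minutes on
one CPU.

## Known limitations

- Absolute exit rates are identifiable only up to Λ/Σr (death is
  unobservable); all reported quantities are ratios or scaled curves.
- The geometric founder-size and single-donor defaults understate
  between-donor variability; per-donor analyses pool nothing across
  donors (unique VDJs are donor-scoped by construction).
- The x_c generative-recovery check uses one-directional leakage; with
  symmetric leakage, lineages homed in the target tissue contaminate the
  small-x end of the discovery curve (found ≈ 1), a real feature of such
  data that biases naive parameter recovery low and is deliberately left
  visible in the symmetric-config analysis scripts.
- Chi-square GOF bins are truncated where expected counts fall below 5;
  rarer cell types are tested on correspondingly shorter m ranges.
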