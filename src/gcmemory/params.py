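"""Parameter blocks for the germinal-center repertoire simulator.

The simulator views affinity maturation as a discrete-time process: in each
germinal-center cycle a B cell either dies, exits as one of the differentiated
cell types, or survives the cycle and accrues hypermutations.  All parameters
are per-cycle probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "GCParams",
    "LocalizationParams",
    "BurstParams",
    "SamplingParams",
    "DEFAULT_EXIT_RATES",
]

#: Default per-cycle exit rates.  Memory exceeds the pooled ASC rate by 40%
#: (0.014 vs 0.010), the headline relative rate of memory vs ASC creation.
DEFAULT_EXIT_RATES: dict[str, float] = {
    "Memory": 0.014,
    "ASC-1": 0.0025,
    "ASC-2": 0.0020,
    "ASC-3": 0.0030,
    "ASC-4": 0.0025,
}


def _check_prob(name: str, value: float, *, closed_low: bool = True) -> None:
    lo_ok = value >= 0 if closed_low else value > 0
    if not (lo_ok and value <= 1):
        raise ValueError(f"{name} must be a probability, got {value!r}")


@dataclass(frozen=True)
class GCParams:
    """Per-cycle germinal-center event rates.

    Parameters
    ----------
    exit_rates
        Map from differentiated cell-type label (naive excluded) to the
        per-cycle probability of exiting the germinal center as that type.
    death_rate
        Per-cycle probability of death (unobservable in sampled repertoires).
    mutations_per_cycle
        Mean number of V-region hypermutations accrued per surviving cycle.
        With the default deterministic distribution this must be 1, making the
        hypermutation count m interchangeable with the cycle index.
    mutation_dist
        ``"deterministic"`` (default) or ``"poisson"``.
    suppression_factor
        Multiplier in (0, 1] applied to all exit rates (not death) while a
        cell's hypermutation count is below ``m_stab``.  Models the observed
        equal-multiplicative-factor reduction of exit rates at low m.
    m_stab
        Hypermutation threshold above which exit rates take their long-term
        values (default 10).
    lineage_rate_dispersion
        Scale of a positive, mean-one per-lineage multiplier applied to the
        total event rate (gamma distributed with this coefficient of
        variation).  Relative exit rates within a lineage are preserved.
    maturation_type_coupling
        Exponent kappa >= 0 tilting the per-lineage ASC share of exits by
        g**-kappa, where g is the lineage rate multiplier: slow-maturing
        (high-m) lineages become ASC-richer.  Within a lineage the tilt is
        constant over cycles, so within-lineage type/label assortment stays
        uniform while repertoire-level hypermutation differs between types
        (Simpson's-paradox structure).  Default 0 (no coupling).
    max_cycles
        Hard cap on cycles; cells still in the GC at the cap are discarded
        and counted in the attrition statistic.
    """

    exit_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXIT_RATES)
    )
    death_rate: float = 0.026
    mutations_per_cycle: float = 1.0
    mutation_dist: str = "deterministic"
    suppression_factor: float = 1.0
    m_stab: int = 10
    lineage_rate_dispersion: float = 0.0
    maturation_type_coupling: float = 0.0
    max_cycles: int = 600

    def __post_init__(self) -> None:
        if not self.exit_rates:
            raise ValueError("exit_rates must name at least one cell type")
        for label, rate in self.exit_rates.items():
            _check_prob(f"exit_rates[{label!r}]", rate)
            if label.lower() == "naive":
                raise ValueError("Naive is not a germinal-center exit type")
        _check_prob("death_rate", self.death_rate)
        _check_prob("suppression_factor", self.suppression_factor, closed_low=False)
        if self.total_event_rate > 1:
            raise ValueError(
                "total per-cycle event probability "
                f"{self.total_event_rate:.4f} exceeds 1; reduce exit/death rates"
            )
        if self.m_stab < 0:
            raise ValueError("m_stab must be >= 0")
        if self.mutations_per_cycle < 0:
            raise ValueError("mutations_per_cycle must be >= 0")
        if self.mutation_dist not in ("deterministic", "poisson"):
            raise ValueError(f"unknown mutation_dist {self.mutation_dist!r}")
        if self.mutation_dist == "deterministic" and self.mutations_per_cycle != int(
            self.mutations_per_cycle
        ):
            raise ValueError("deterministic mutations_per_cycle must be an integer")
        if self.lineage_rate_dispersion < 0 or self.maturation_type_coupling < 0:
            raise ValueError("dispersion/coupling must be >= 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(self.exit_rates)

    @property
    def total_exit_rate(self) -> float:
        return float(sum(self.exit_rates.values()))

    @property
    def total_event_rate(self) -> float:
        """Per-cycle probability of any event (exit or death), unsuppressed."""
        return self.total_exit_rate + self.death_rate

    @property
    def low_event_rate(self) -> float:
        """Per-cycle event probability while m < m_stab."""
        return self.suppression_factor * self.total_exit_rate + self.death_rate


@dataclass(frozen=True)
class LocalizationParams:
    """Lineage homing and rare per-cell leakage between tissues.

    Each lineage is assigned a single home tissue drawn from ``home_weights``;
    every exiting cell settles there except with a small per-cell probability
    ``leak_prob[(home, other)]`` of settling in ``other`` instead.
    """

    tissues: Sequence[str] = ("BM", "Spleen", "LN", "Blood")
    home_weights: Sequence[float] | None = None
    leak_prob: Mapping[tuple[str, str], float] | float = 0.0

    def __post_init__(self) -> None:
        if len(self.tissues) == 0:
            raise ValueError("need at least one tissue")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        if self.home_weights is not None:
            if len(self.home_weights) != len(self.tissues):
                raise ValueError("home_weights length must match tissues")
            total = float(sum(self.home_weights))
            if abs(total - 1.0) > 1e-9 or min(self.home_weights) < 0:
                raise ValueError("home_weights must be a probability vector")
        for (a, b), p in self.leak_map().items():
            _check_prob(f"leak_prob[{(a, b)!r}]", p)
            if a not in self.tissues or b not in self.tissues:
                raise ValueError(f"leak_prob names unknown tissue in {(a, b)!r}")
            if a == b:
                raise ValueError("leak_prob keys must be distinct tissue pairs")

    def weights(self) -> list[float]:
        if self.home_weights is None:
            n = len(self.tissues)
            return [1.0 / n] * n
        return [float(w) for w in self.home_weights]

    def leak_map(self) -> dict[tuple[str, str], float]:
        """Leak probabilities as an explicit (home, other) -> p map."""
        if isinstance(self.leak_prob, Mapping):
            return {tuple(k): float(v) for k, v in self.leak_prob.items()}
        p = float(self.leak_prob)
        return {
            (a, b): p for a in self.tissues for b in self.tissues if a != b
        }


@dataclass(frozen=True)
class BurstParams:
    """Correlated ASC-3 clonal bursts.

    A random subset of lineages is burst-prone; in each such lineage an
    existing member clone is expanded into many identical-sequence ASC-3
    cells (clonal expansion without further hypermutation), optionally
    distributed across all tissues.
    """

    burst_lineage_prob: float = 0.0
    burst_size_mean: float = 20.0
    clones_per_lineage: int = 1
    multi_tissue_burst: bool = True
    exclude_naive_lineages: bool = False

    def __post_init__(self) -> None:
        _check_prob("burst_lineage_prob", self.burst_lineage_prob)
        if self.burst_size_mean < 1:
            raise ValueError("burst_size_mean must be >= 1")
        if self.clones_per_lineage < 1:
            raise ValueError("clones_per_lineage must be >= 1")


@dataclass(frozen=True)
class SamplingParams:
    """Emulsion-based subsampling of the cell suspension.

    Cells are partitioned by tissue, assigned uniformly at random to one of
    ``emulsions_per_tissue`` droplet emulsions, and captured independently
    with probability ``capture_prob``.  ``cells_per_emulsion`` > 0 caps each
    emulsion's cell count (excess cells are dropped uniformly).
    """

    emulsions_per_tissue: int = 2
    cells_per_emulsion: int = 0
    capture_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.emulsions_per_tissue < 1:
            raise ValueError("emulsions_per_tissue must be >= 1")
        if self.cells_per_emulsion < 0:
            raise ValueError("cells_per_emulsion must be >= 0")
        _check_prob("capture_prob", self.capture_prob)
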