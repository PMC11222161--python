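"""Replication-coupled passive demethylation model and rate estimators.

Each CpG site is a binary state that is diluted at every cell cycle: a
methylated site stays methylated with probability ``p_maint`` (maintenance
methyltransferase activity at the replication fork) and an unmethylated site
gains methylation with probability ``p_denovo`` (de novo activity).  The
expected bulk level on the [0,1] scale follows

    m_{t+1} = m_t * p_maint + (1 - m_t) * p_denovo

with closed form m_t = e + (m_0 - e) * (p_maint - p_denovo)^t and
equilibrium e = p_denovo / (1 - p_maint + p_denovo).

The per-cycle demethylation rate is reported primarily as the linear
absolute loss (percentage points of 5mC per cell cycle), matching the
printed "% per cell cycle" framing, with the geometric per-cycle retention
as a secondary readout.  Cell-cycle counts come from a culture clock of
per-passage-interval doubling times, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ProbabilityError(ValueError):
    """A methylation transition probability outside [0, 1]."""


class ClockError(ValueError):
    """A culture clock with no elapsed cell cycles."""


class DegenerateGroupsError(ValueError):
    """Effect size undefined (zero pooled SD or group too small)."""


@dataclass
class DilutionParams:
    """Per-cycle transition probabilities of the dilution model."""

    p_maint: float
    p_denovo: float = 0.0
    n_cycles: int = 0
    initial_level: float = 85.0  # percent

    def __post_init__(self) -> None:
        for name in ("p_maint", "p_denovo"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ProbabilityError(f"{name}={p} outside [0, 1]")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")

    @property
    def equilibrium(self) -> float:
        """Long-run bulk methylation level (fraction)."""
        denom = 1.0 - self.p_maint + self.p_denovo
        return self.p_denovo / denom if denom > 0 else 1.0

    def expected_trajectory(self, n_cycles: int | None = None) -> np.ndarray:
        """Closed-form expected bulk level (fraction) per cycle, incl. cycle 0."""
        n = self.n_cycles if n_cycles is None else n_cycles
        t = np.arange(n + 1)
        e = self.equilibrium
        m0 = self.initial_level / 100.0
        return e + (m0 - e) * (self.p_maint - self.p_denovo) ** t


@dataclass
class CultureClock:
    """Per-passage-interval (days, doubling_time_days) pairs."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def elapsed_days(self) -> float:
        return sum(d for d, _ in self.intervals)

    @property
    def n_cycles(self) -> float:
        n = sum(days / dt for days, dt in self.intervals)
        if self.elapsed_days > 0 and n <= 0:
            raise ClockError("elapsed time but no cell cycles")
        return n


def params_for_linear_rate(initial_level: float, rate_per_cycle: float,
                           n_cycles: float) -> DilutionParams:
    """Maintenance probability whose trajectory realises a linear loss.

    Given a starting bulk level (percent), a target absolute loss in
    percentage points per cycle and a clock length, returns the p_denovo=0
    dilution parameters whose endpoint reproduces that linear rate:
    p_maint = (m_end / m_start)^(1/n) with m_end = m_start - rate * n.
    """
    m_end = initial_level - rate_per_cycle * n_cycles
    if not (0.0 < m_end <= initial_level):
        raise ValueError("rate and clock imply an endpoint outside (0, m_start]")
    p_maint = float((m_end / initial_level) ** (1.0 / n_cycles))
    return DilutionParams(p_maint=p_maint, p_denovo=0.0,
                          n_cycles=int(round(n_cycles)), initial_level=initial_level)


def simulate_dilution(params: DilutionParams, n_sites: int,
                      rng: np.random.Generator,
                      p_maint_per_site: np.ndarray | None = None) -> np.ndarray:
    """Binary per-site methylation states per cycle.

    Returns a (n_cycles + 1, n_sites) boolean array; row 0 is the initial
    state drawn Bernoulli(initial_level/100).  ``p_maint_per_site`` allows
    class-specific maintenance overrides (e.g. escapee retention = 1).
    """
    pm = np.full(n_sites, params.p_maint) if p_maint_per_site is None \
        else np.asarray(p_maint_per_site, dtype=float)
    if pm.shape != (n_sites,):
        raise ValueError("p_maint_per_site must have one value per site")
    if ((pm < 0) | (pm > 1)).any():
        raise ProbabilityError("per-site p_maint outside [0, 1]")
    states = np.empty((params.n_cycles + 1, n_sites), dtype=bool)
    states[0] = rng.random(n_sites) < params.initial_level / 100.0
    for t in range(params.n_cycles):
        prev = states[t]
        keep = rng.random(n_sites) < pm
        gain = rng.random(n_sites) < params.p_denovo
        states[t + 1] = np.where(prev, keep, gain)
    return states


@dataclass
class PerCycleRate:
    linear_pct_per_cycle: float
    geometric_retention: float | None
    n_cycles: float
    geometric_defined: bool = True


def estimate_per_cycle_rate(m_start: float, m_end: float,
                            clock: CultureClock) -> PerCycleRate:
    """Linear absolute 5mC loss per cell cycle, plus geometric retention.

    ``linear`` = (m_start - m_end) / n_cycles in percentage points per cycle;
    ``geometric_retention`` = (m_end / m_start)^(1/n).  A zero start level
    leaves the geometric readout undefined (flagged, not raised).
    """
    n = clock.n_cycles
    if n <= 0:
        raise ClockError("cannot estimate a per-cycle rate over zero cycles")
    linear = (m_start - m_end) / n
    if m_start <= 0:
        return PerCycleRate(linear, None, n, geometric_defined=False)
    retention = float((max(m_end, 0.0) / m_start) ** (1.0 / n))
    return PerCycleRate(float(linear), retention, n)


def cohens_d(group_a, group_b) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD with (n-1) weighting."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateGroupsError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise DegenerateGroupsError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
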