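"""Discrete-time Markov cohort engine.

A closed cohort is pushed through a sequence of per-cycle transition
matrices (age-dependent matrices are simply a different matrix per cycle)
and rewards (costs, utilities, life years) are accrued per cycle with
differential discounting of costs and health outcomes.

Conventions
-----------
* Occupancy is continuous (expected person-counts); the cohort size is a
  scale factor only and all accrued totals are reported per person.
* All rewards are end-of-cycle: the occupancy at the *end* of cycle ``t``
  earns that cycle's state rewards, discounted by ``(1 + r)^-t``.  The
  initial (cycle-0) distribution accrues nothing, and a death during a
  cycle earns no partial-year reward.  There is no half-cycle correction.
* One-time event costs (e.g. the cost of a fatal bleeding episode) are
  attached to the state occupied at the *start* of the cycle in which the
  event may occur, as an expected cost per occupant
  (:attr:`RewardSchedule.entry_cost`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "HealthState",
    "StateSpace",
    "TransitionMatrix",
    "CohortTrace",
    "RewardSchedule",
    "DiscountSpec",
    "Totals",
    "step_cohort",
    "run_cohort",
    "discount_factor",
    "accrue_outcomes",
    "trace_frame",
    "write_trace_csv",
]

#: row-stochasticity tolerance for transition matrices
ROW_TOL = 1e-12
#: cohort-conservation tolerance, relative to cohort size
CONSERVATION_TOL = 1e-9


class ConfigurationError(ValueError):
    """A model input is structurally inconsistent (missing matrix, reward, ...)."""


@dataclass(frozen=True)
class HealthState:
    """One mutually exclusive health state.

    ``temporary`` marks a tunnel state: occupants must leave after exactly
    one cycle, so its self-transition probability is 0 in every matrix.
    """

    name: str
    absorbing: bool = False
    temporary: bool = False


@dataclass(frozen=True)
class StateSpace:
    """Ordered collection of health states with exactly one absorbing state."""

    states: tuple[HealthState, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate state names: %r" % (names,))
        n_abs = sum(s.absorbing for s in self.states)
        if n_abs != 1:
            raise ConfigurationError(
                f"exactly one absorbing state required, got {n_abs}"
            )

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def absorbing_index(self) -> int:
        return next(i for i, s in enumerate(self.states) if s.absorbing)

    @property
    def alive_mask(self) -> np.ndarray:
        """1.0 for every non-absorbing state, 0.0 for the absorbing one."""
        return np.array([0.0 if s.absorbing else 1.0 for s in self.states])


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic per-cycle matrix; entry ``[i, j]`` is P(i -> j)."""

    cycle_index: int
    probs: np.ndarray
    space: StateSpace

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise ValueError(f"cycle_index must be >= 1, got {self.cycle_index}")
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        n = self.space.n
        if p.shape != (n, n):
            raise ConfigurationError(f"matrix shape {p.shape} != ({n}, {n})")
        if (p < -ROW_TOL).any() or (p > 1 + ROW_TOL).any():
            raise ConfigurationError("transition probabilities outside [0, 1]")
        rows = p.sum(axis=1)
        if np.abs(rows - 1.0).max() > ROW_TOL:
            raise ConfigurationError(
                f"rows must sum to 1 within {ROW_TOL}; sums: {rows}"
            )
        k = self.space.absorbing_index
        ident = np.zeros(n)
        ident[k] = 1.0
        if not np.allclose(p[k], ident, atol=ROW_TOL):
            raise ConfigurationError("absorbing state row must be the identity row")
        for i, s in enumerate(self.space.states):
            if s.temporary and p[i, i] != 0.0:
                raise ConfigurationError(
                    f"temporary state {s.name!r} has non-zero self-transition"
                )


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle; row 0 is the initial distribution."""

    occupancy: np.ndarray  # shape (n_cycles + 1, n_states), persons
    space: StateSpace
    cohort_size: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        totals = occ.sum(axis=1)
        if np.abs(totals - self.cohort_size).max() > CONSERVATION_TOL * self.cohort_size:
            raise ConfigurationError("cohort not conserved across cycles")
        dead = occ[:, self.space.absorbing_index]
        if (np.diff(dead) < -CONSERVATION_TOL * self.cohort_size).any():
            raise ConfigurationError("absorbing-state occupancy decreased")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def fractions(self) -> np.ndarray:
        return self.occupancy / self.cohort_size

    def alive(self) -> np.ndarray:
        """Persons alive at the end of each cycle (length ``n_cycles + 1``)."""
        return self.occupancy @ self.space.alive_mask

    def to_frame(self) -> pd.DataFrame:
        n1, s = self.occupancy.shape
        return pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(n1), s),
                "state": np.tile(self.space.names, n1),
                "occupancy": self.occupancy.ravel(),
            }
        )


@dataclass(frozen=True)
class RewardSchedule:
    """Per-cycle, per-state rewards.

    ``state_cost`` and ``state_utility`` apply to end-of-cycle occupancy;
    ``entry_cost`` is the expected one-time cost per occupant of a state at
    the start of the cycle (used for event costs such as a fatal adverse
    event).  Row ``t - 1`` of each array belongs to cycle ``t``.
    """

    state_cost: np.ndarray  # (n_cycles, n_states), USD
    state_utility: np.ndarray  # (n_cycles, n_states), in [0, 1]
    entry_cost: np.ndarray  # (n_cycles, n_states), USD
    space: StateSpace

    def __post_init__(self) -> None:
        for name in ("state_cost", "state_utility", "entry_cost"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 2 or arr.shape[1] != self.space.n:
                raise ConfigurationError(f"{name} must be (n_cycles, {self.space.n})")
        if not (
            self.state_cost.shape == self.state_utility.shape == self.entry_cost.shape
        ):
            raise ConfigurationError("reward arrays must share one shape")
        u = self.state_utility
        if (u < 0).any() or (u > 1).any():
            raise ConfigurationError("utilities must lie in [0, 1]")
        if u[:, self.space.absorbing_index].any():
            raise ConfigurationError("utility of the absorbing state must be 0")

    @property
    def n_cycles(self) -> int:
        return self.state_cost.shape[0]


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rates; costs and outcomes may differ."""

    cost_rate: float = 0.05
    outcome_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.cost_rate < 0 or self.outcome_rate < 0:
            raise ValueError("discount rates must be >= 0")


@dataclass(frozen=True)
class Totals:
    """Discounted per-person totals over the whole horizon."""

    cost: float
    qaly: float
    ly: float


def step_cohort(occupancy: np.ndarray, matrix: TransitionMatrix) -> np.ndarray:
    """Advance the cohort one cycle: returns ``occupancy @ matrix.probs``."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (matrix.space.n,):
        raise ConfigurationError(
            f"occupancy shape {occ.shape} does not match {matrix.space.n} states"
        )
    if (occ < 0).any():
        raise ValueError("occupancy must be non-negative")
    return occ @ matrix.probs


def run_cohort(
    initial: np.ndarray,
    matrices: Sequence[TransitionMatrix],
    n_cycles: int | None = None,
) -> CohortTrace:
    """Run the cohort through one matrix per cycle and record the trace."""
    if n_cycles is None:
        n_cycles = len(matrices)
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if len(matrices) < n_cycles:
        raise ConfigurationError(
            f"{n_cycles} cycles requested but only {len(matrices)} matrices supplied"
        )
    space = matrices[0].space
    occ = np.asarray(initial, dtype=float)
    trace = np.empty((n_cycles + 1, space.n))
    trace[0] = occ
    for t in range(1, n_cycles + 1):
        occ = step_cohort(occ, matrices[t - 1])
        trace[t] = occ
    return CohortTrace(occupancy=trace, space=space, cohort_size=float(trace[0].sum()))


def discount_factor(rate: float, cycle: int) -> float:
    """End-of-year discount factor ``1 / (1 + rate)^cycle`` (cycle >= 1)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    return (1.0 + rate) ** (-cycle)


def accrue_outcomes(
    trace: CohortTrace, rewards: RewardSchedule, discount: DiscountSpec
) -> Totals:
    """Discounted per-person cost, QALY and LY totals for a finished trace.

    Life years use weight 1 for every alive state (the adverse-event tunnel
    state counts as a full alive year).
    """
    if rewards.n_cycles < trace.n_cycles:
        raise ConfigurationError(
            f"rewards cover {rewards.n_cycles} cycles, trace has {trace.n_cycles}"
        )
    alive = trace.space.alive_mask
    occ = trace.occupancy
    cost = qaly = ly = 0.0
    for t in range(1, trace.n_cycles + 1):
        vc = discount_factor(discount.cost_rate, t)
        vo = discount_factor(discount.outcome_rate, t)
        cost += vc * (
            occ[t] @ rewards.state_cost[t - 1] + occ[t - 1] @ rewards.entry_cost[t - 1]
        )
        qaly += vo * (occ[t] @ rewards.state_utility[t - 1])
        ly += vo * (occ[t] @ alive)
    n = trace.cohort_size
    return Totals(cost=cost / n, qaly=qaly / n, ly=ly / n)


def trace_frame(
    trace: CohortTrace, rewards: RewardSchedule, discount: DiscountSpec
) -> pd.DataFrame:
    """Tidy per-cycle, per-state table of occupancy and discounted accruals."""
    rows = []
    occ = trace.occupancy
    for t in range(trace.n_cycles + 1):
        vc = discount_factor(discount.cost_rate, t) if t >= 1 else 0.0
        vo = discount_factor(discount.outcome_rate, t) if t >= 1 else 0.0
        for j, name in enumerate(trace.space.names):
            if t >= 1:
                dcost = vc * (
                    occ[t, j] * rewards.state_cost[t - 1, j]
                    + occ[t - 1, j] * rewards.entry_cost[t - 1, j]
                )
                dqaly = vo * occ[t, j] * rewards.state_utility[t - 1, j]
            else:
                dcost = dqaly = 0.0
            rows.append(
                {
                    "cycle": t,
                    "state": name,
                    "occupancy": occ[t, j],
                    "discounted_cost": dcost,
                    "discounted_qaly": dqaly,
                }
            )
    return pd.DataFrame(rows)


def write_trace_csv(
    path, trace: CohortTrace, rewards: RewardSchedule, discount: DiscountSpec
) -> None:
    trace_frame(trace, rewards, discount).to_csv(path, index=False)
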