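"""Five-state adjuvant-therapy models for Stage I and II colorectal cancer.

States: remission on the assigned intervention, a one-cycle tunnel state
for treatment of a non-fatal adverse event (AE), remission after unplanned
treatment discontinuation, incurable recurrence, and death.  Cycles are
one year; the cohort enters in remission at age 65 and is followed for 20
years.

Competing events within a cycle are resolved as an event tree with
conditional probabilities, so each row is exactly stochastic:

1. fatal AE (active treatment, within the treatment window),
2. death from other causes (age-dependent background mortality),
3. non-fatal grade 3/4 AE -> one-cycle tunnel, then unplanned
   discontinuation,
4. recurrence (relative risk of the active arm applied within the benefit
   window; unmodified natural history after discontinuation),
5. otherwise remain.

Patients who discontinue lose both AE risk and treatment benefit; no
transition from recurrence back to remission is permitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import CostInputs, StrategyResult, CeResult, compute_icer
from .model_core import (
    CohortTrace,
    ConfigurationError,
    DiscountSpec,
    HealthState,
    RewardSchedule,
    StateSpace,
    Totals,
    TransitionMatrix,
    accrue_outcomes,
    run_cohort,
)

__all__ = [
    "FIVE_STATES",
    "REMISSION",
    "AE_TUNNEL",
    "DISCONTINUED",
    "RECURRENCE",
    "DEATH",
    "NaturalHistory",
    "StrategySpec",
    "ModelConfig",
    "UtilityInputs",
    "StrategyOutcome",
    "ModelBundle",
    "apply_relative_risk",
    "build_transition_matrix",
    "assemble_strategy",
    "run_strategy",
]

FIVE_STATES = StateSpace(
    (
        HealthState("remission_intervention"),
        HealthState("ae_treatment", temporary=True),
        HealthState("remission_discontinued"),
        HealthState("recurrence"),
        HealthState("death", absorbing=True),
    )
)

REMISSION = FIVE_STATES.index("remission_intervention")
AE_TUNNEL = FIVE_STATES.index("ae_treatment")
DISCONTINUED = FIVE_STATES.index("remission_discontinued")
RECURRENCE = FIVE_STATES.index("recurrence")
DEATH = FIVE_STATES.index("death")


@dataclass
class NaturalHistory:
    """Age-indexed annual transition probabilities of the untreated disease.

    ``ages`` holds the age at the *start* of each cycle; the three
    probability arrays are aligned with it.  ``p_rec`` is remission ->
    recurrence, ``p_death_other`` is background (other-cause) mortality and
    ``p_death_rec`` is post-recurrence mortality.
    """

    stage: str
    ages: np.ndarray
    p_rec: np.ndarray
    p_death_other: np.ndarray
    p_death_rec: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        for name in ("p_rec", "p_death_other", "p_death_rec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.ages.shape:
                raise ConfigurationError(f"{name} must align with ages")
            if (arr < 0).any() or (arr > 1).any():
                raise ConfigurationError(f"{name} outside [0, 1]")
        if (self.p_rec + self.p_death_other > 1).any():
            raise ConfigurationError("p_rec + p_death_other exceeds 1 at some age")

    def _idx(self, age: int) -> int:
        hits = np.nonzero(self.ages == age)[0]
        if hits.size == 0:
            raise ConfigurationError(
                f"age {age} outside natural-history support "
                f"[{self.ages.min()}, {self.ages.max()}]"
            )
        return int(hits[0])

    def at_age(self, age: int) -> tuple[float, float, float]:
        i = self._idx(age)
        return float(self.p_rec[i]), float(self.p_death_other[i]), float(self.p_death_rec[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "p_rec": self.p_rec,
                "p_death_other": self.p_death_other,
                "p_death_rec": self.p_death_rec,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stage: str) -> "NaturalHistory":
        return cls(
            stage=stage,
            ages=frame["age"].to_numpy(),
            p_rec=frame["p_rec"].to_numpy(),
            p_death_other=frame["p_death_other"].to_numpy(),
            p_death_rec=frame["p_death_rec"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path, stage: str) -> "NaturalHistory":
        return cls.from_frame(pd.read_csv(path), stage=stage)


@dataclass
class StrategySpec:
    """One treatment arm.

    Per-cycle arrays are indexed by cycle (row ``t - 1`` is cycle ``t``)
    and already encode the drug-cost window; AE probabilities are gated by
    ``treatment_years`` at matrix-build time, the relative risk by
    ``benefit_years``.  ``pill_utility`` multiplies the remission utility
    during treatment (daily-pill disutility; 1.0 = none).
    """

    name: str
    horizon: int
    rr_progression: float = 1.0
    benefit_years: int = 0
    treatment_years: int = 0
    pill_utility: float = 1.0
    p_fatal_ae: np.ndarray = None  # type: ignore[assignment]
    p_nonfatal_ae: np.ndarray = None  # type: ignore[assignment]
    drug_cost: np.ndarray = None  # type: ignore[assignment]
    ae_nonfatal_cost: np.ndarray = None  # type: ignore[assignment]
    ae_fatal_cost: np.ndarray = None  # type: ignore[assignment]
    extra_visits: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rr_progression <= 0:
            raise ValueError(f"rr_progression must be > 0, got {self.rr_progression}")
        if not 0 <= self.pill_utility <= 1:
            raise ValueError("pill_utility must lie in [0, 1]")
        for name in (
            "p_fatal_ae",
            "p_nonfatal_ae",
            "drug_cost",
            "ae_nonfatal_cost",
            "ae_fatal_cost",
            "extra_visits",
        ):
            arr = getattr(self, name)
            arr = np.zeros(self.horizon) if arr is None else np.asarray(arr, dtype=float)
            if arr.shape != (self.horizon,):
                raise ConfigurationError(f"{name} must have length {self.horizon}")
            setattr(self, name, arr)
        for name in ("p_fatal_ae", "p_nonfatal_ae"):
            arr = getattr(self, name)
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} outside [0, 1]")
        if (self.p_fatal_ae + self.p_nonfatal_ae > 1).any():
            raise ValueError("p_fatal_ae + p_nonfatal_ae exceeds 1 in some cycle")

    @classmethod
    def no_treatment(cls, horizon: int) -> "StrategySpec":
        """Comparator arm: relative risk 1, no AEs, no drug cost."""
        return cls(name="no_treatment", horizon=horizon)


@dataclass(frozen=True)
class ModelConfig:
    """Cohort- and analysis-level settings."""

    stage: str
    start_age: int = 65
    horizon: int = 20
    cohort_size: float = 10_000.0
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    wtp: float = 100_000.0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class UtilityInputs:
    """Stage-specific utility weights.

    The tunnel-state utility is not published; it defaults to the
    discontinued-remission utility (occupants have stopped treatment).
    """

    remission_intervention: float
    remission_discontinued: float
    recurrence: float
    ae_treatment: float | None = None

    def __post_init__(self) -> None:
        if self.ae_treatment is None:
            self.ae_treatment = self.remission_discontinued
        for name in ("remission_intervention", "remission_discontinued", "recurrence", "ae_treatment"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"utility {name} outside [0, 1]: {v}")


def apply_relative_risk(p: float, rr: float) -> float:
    """Multiply a progression probability by a relative risk, capped at 1."""
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    if not 0 <= p <= 1:
        raise ValueError(f"probability outside [0, 1]: {p}")
    scaled = rr * p
    if scaled > 1:
        warnings.warn(
            f"relative risk {rr} drives probability {p} above 1; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return scaled


def build_transition_matrix(
    cycle: int,
    nh: NaturalHistory,
    strat: StrategySpec,
    config: ModelConfig,
) -> TransitionMatrix:
    """Assemble the five-state matrix of one cycle for one strategy."""
    if not 1 <= cycle <= config.horizon:
        raise ValueError(f"cycle {cycle} outside horizon 1..{config.horizon}")
    age = config.start_age + cycle - 1
    p_rec_raw, p_do, p_dr = nh.at_age(age)

    on_treatment = cycle <= strat.treatment_years
    in_benefit = cycle <= strat.benefit_years
    p_f = float(strat.p_fatal_ae[cycle - 1]) if on_treatment else 0.0
    p_nf = float(strat.p_nonfatal_ae[cycle - 1]) if on_treatment else 0.0
    rr = strat.rr_progression if in_benefit else 1.0
    p_rec_mod = apply_relative_risk(p_rec_raw, rr)

    m = np.zeros((5, 5))
    # remission on intervention: fatal AE, then other-cause death, then
    # non-fatal AE, then recurrence; residual stays.
    d = p_f + (1 - p_f) * p_do
    ae = (1 - p_f) * (1 - p_do) * p_nf
    rec = (1 - p_f) * (1 - p_do) * (1 - p_nf) * p_rec_mod
    m[REMISSION, DEATH] = d
    m[REMISSION, AE_TUNNEL] = ae
    m[REMISSION, RECURRENCE] = rec
    m[REMISSION, REMISSION] = 1.0 - d - ae - rec

    # AE tunnel (temporary): occupants are alive and at natural-history
    # risk during the tunnel year (treatment already stopped -> no AE risk,
    # no benefit), then land in discontinued remission.
    rec_t = (1 - p_do) * p_rec_raw
    m[AE_TUNNEL, DEATH] = p_do
    m[AE_TUNNEL, RECURRENCE] = rec_t
    m[AE_TUNNEL, DISCONTINUED] = 1.0 - p_do - rec_t

    # discontinued remission: pure natural history.
    m[DISCONTINUED, DEATH] = p_do
    m[DISCONTINUED, RECURRENCE] = rec_t
    m[DISCONTINUED, DISCONTINUED] = 1.0 - p_do - rec_t

    # recurrence: incurable; death only.
    m[RECURRENCE, DEATH] = p_dr
    m[RECURRENCE, RECURRENCE] = 1.0 - p_dr

    m[DEATH, DEATH] = 1.0
    return TransitionMatrix(cycle_index=cycle, probs=m, space=FIVE_STATES)


def assemble_strategy(
    config: ModelConfig,
    strat: StrategySpec,
    nh: NaturalHistory,
    costs: CostInputs,
    utils: UtilityInputs,
) -> tuple[list[TransitionMatrix], RewardSchedule]:
    """Per-cycle matrices plus the matching reward schedule for one arm."""
    n = config.horizon
    matrices = [build_transition_matrix(t, nh, strat, config) for t in range(1, n + 1)]

    state_cost = np.zeros((n, 5))
    state_utility = np.zeros((n, 5))
    entry_cost = np.zeros((n, 5))
    for t in range(1, n + 1):
        i = t - 1
        surv = costs.surveillance_cost(t)
        ind_rem = costs.indirect_remission(t)
        state_cost[i, REMISSION] = (
            costs.surveillance_cost(t, extra_visits=float(strat.extra_visits[i]))
            + strat.drug_cost[i]
            + ind_rem
        )
        state_cost[i, AE_TUNNEL] = surv + ind_rem + strat.ae_nonfatal_cost[i]
        state_cost[i, DISCONTINUED] = surv + ind_rem
        state_cost[i, RECURRENCE] = (
            surv
            + costs.colonoscopy_cost(t)
            + costs.metastatic_annual
            + costs.indirect_recurrence(t)
        )
        # fatal-AE episode cost: expected one-time cost per remission
        # occupant at the start of the cycle.
        on_treatment = t <= strat.treatment_years
        p_f = float(strat.p_fatal_ae[i]) if on_treatment else 0.0
        entry_cost[i, REMISSION] = p_f * strat.ae_fatal_cost[i]

        pill = strat.pill_utility if t <= strat.treatment_years else 1.0
        state_utility[i, REMISSION] = utils.remission_intervention * pill
        state_utility[i, AE_TUNNEL] = utils.ae_treatment
        state_utility[i, DISCONTINUED] = utils.remission_discontinued
        state_utility[i, RECURRENCE] = utils.recurrence

    rewards = RewardSchedule(
        state_cost=state_cost,
        state_utility=state_utility,
        entry_cost=entry_cost,
        space=FIVE_STATES,
    )
    return matrices, rewards


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-person discounted totals plus the underlying trace."""

    name: str
    totals: Totals
    trace: CohortTrace

    @property
    def result(self) -> StrategyResult:
        return StrategyResult(
            name=self.name, cost=self.totals.cost, qaly=self.totals.qaly, ly=self.totals.ly
        )


def run_strategy(
    config: ModelConfig,
    strat: StrategySpec,
    nh: NaturalHistory,
    costs: CostInputs,
    utils: UtilityInputs,
) -> StrategyOutcome:
    """assemble -> run -> accrue for one arm."""
    matrices, rewards = assemble_strategy(config, strat, nh, costs, utils)
    initial = np.zeros(5)
    initial[REMISSION] = config.cohort_size
    trace = run_cohort(initial, matrices)
    totals = accrue_outcomes(trace, rewards, config.discount)
    return StrategyOutcome(name=strat.name, totals=totals, trace=trace)


@dataclass
class ModelBundle:
    """Everything needed to evaluate one stage's model: config, natural
    history, strategies, costs and utilities.  Sensitivity analyses mutate
    deep copies of a bundle through dotted parameter paths."""

    config: ModelConfig
    nh: NaturalHistory
    strategies: dict[str, StrategySpec]
    costs: CostInputs
    utilities: UtilityInputs

    def run(self) -> dict[str, StrategyOutcome]:
        return {
            name: run_strategy(self.config, strat, self.nh, self.costs, self.utilities)
            for name, strat in self.strategies.items()
        }

    def ce_result(self, reference: str = "aspirin") -> CeResult:
        outcomes = self.run()
        return compute_icer([o.result for o in outcomes.values()], reference=reference)
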