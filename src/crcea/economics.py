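"""Cost-input derivations and incremental cost-effectiveness analysis.

Costs are expressed in November-2013 US dollars.  Source amounts from
earlier years are converted with the medical-care consumer price index
(CPI) factors published for November 2013.  Where the published 2013
value and the raw-source recomputation disagree by more than a dollar
(rounding drift in the source material), the published value is kept as
authoritative and the item is flagged (:func:`check_cost_derivations`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CPI_MEDICAL_2013",
    "inflate_cost",
    "annualize",
    "time_cost",
    "weighted_ae_cost",
    "report_dollars",
    "CostItem",
    "CostInputs",
    "StrategyResult",
    "Comparison",
    "CeResult",
    "compute_icer",
    "net_monetary_benefit",
    "dominance_frontier",
    "ce_table",
]

#: Medical-care CPI factors to November 2013 by source year.
CPI_MEDICAL_2013 = {2000: 1.64, 2005: 1.33, 2006: 1.28, 2007: 1.22, 2011: 1.07, 2013: 1.0}


def inflate_cost(amount: float, cpi_factor: float) -> float:
    """Convert a source-year amount to 2013 USD (``amount * cpi_factor``)."""
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount}")
    if cpi_factor <= 0:
        raise ValueError(f"cpi_factor must be > 0, got {cpi_factor}")
    return amount * cpi_factor


def annualize(amount_per_month: float) -> float:
    """Monthly to annual amount."""
    if amount_per_month < 0:
        raise ValueError("amount must be >= 0")
    return amount_per_month * 12.0


def time_cost(hours_per_year: float, wage_per_hour: float) -> float:
    """Indirect (patient-time) cost: hours per year valued at an hourly wage."""
    if hours_per_year < 0 or wage_per_hour < 0:
        raise ValueError("inputs must be >= 0")
    return hours_per_year * wage_per_hour


def weighted_ae_cost(
    event_probs: Sequence[float],
    unit_costs: Sequence[float],
    cpi_factor: float = 1.0,
) -> float:
    """Probability-weighted mean episode cost across event types, inflated to 2013.

    ``sum(p_i * c_i) / sum(p_i) * cpi_factor``.  Raises if every probability
    is zero (the weighted mean is undefined).
    """
    p = np.asarray(event_probs, dtype=float)
    c = np.asarray(unit_costs, dtype=float)
    if p.shape != c.shape:
        raise ValueError("one unit cost per event type required")
    if (p < 0).any():
        raise ValueError("event probabilities must be >= 0")
    if p.sum() == 0:
        raise ValueError("all event probabilities are zero; weighted cost undefined")
    return inflate_cost(float((p * c).sum() / p.sum()), cpi_factor)


def report_dollars(amount: float) -> int:
    """Round to the nearest dollar for reporting (internals stay unrounded)."""
    return int(round(amount))


# ---------------------------------------------------------------------------
# Cost-item audit table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostItem:
    """One cost input with its raw source amount and derivation path.

    ``months`` scales a per-month raw amount to the billed period before
    CPI conversion (12 = annualized, 6 = a six-month regimen, 1 = stays
    monthly).  ``printed_2013`` (the published 2013 value) is authoritative
    when present; ``value_2013`` otherwise falls back to the recomputed
    amount.
    """

    name: str
    raw_amount: float
    source_year: int
    unit: str = "per_year"  # per_year | per_month | per_episode | per_admin
    months: int = 1
    printed_2013: float | None = None
    note: str = ""

    def derived_2013(self) -> float | None:
        factor = CPI_MEDICAL_2013.get(self.source_year)
        if factor is None:
            return None
        base = self.raw_amount * self.months if self.unit == "per_month" else self.raw_amount
        return inflate_cost(base, factor)

    def value_2013(self) -> float:
        if self.printed_2013 is not None:
            return self.printed_2013
        derived = self.derived_2013()
        if derived is None:
            raise ValueError(
                f"{self.name}: no CPI factor for {self.source_year} and no printed value"
            )
        return derived


def check_cost_derivations(items: Iterable[CostItem], tol: float = 1.0) -> pd.DataFrame:
    """Regenerate every item from raw amount x CPI and flag discrepancies > tol USD."""
    rows = []
    for item in items:
        derived = item.derived_2013()
        value = item.value_2013()
        consistent = derived is not None and abs(derived - value) <= tol
        rows.append(
            {
                "item": item.name,
                "raw_amount": item.raw_amount,
                "source_year": item.source_year,
                "derived_2013": derived,
                "value_2013": value,
                "consistent": consistent,
                "note": item.note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-facing resolved cost inputs
# ---------------------------------------------------------------------------


@dataclass
class CostInputs:
    """Resolved 2013-USD cost inputs consumed by the model assembly.

    Surveillance schedules are per-cycle frequency arrays (length =
    horizon); indirect (patient-time) costs apply only while patients are
    assumed to be working (``indirect_years`` cycles, full retirement age).
    """

    physician_visit: float
    blood_test: float
    cea_test: float
    ct_scan: float
    colonoscopy: float
    metastatic_annual: float
    indirect_remission_annual: float
    indirect_recurrence_annual: float
    visit_schedule: np.ndarray  # visits per year, per cycle
    blood_schedule: np.ndarray
    cea_schedule: np.ndarray
    ct_schedule: np.ndarray
    colonoscopy_schedule: np.ndarray  # 0/1 per cycle
    indirect_years: int = 3

    def surveillance_cost(self, cycle: int, extra_visits: float = 0.0) -> float:
        """Surveillance cost of cycle ``cycle`` (1-based), all alive states."""
        i = cycle - 1
        return (
            (self.visit_schedule[i] + extra_visits) * self.physician_visit
            + self.blood_schedule[i] * self.blood_test
            + self.cea_schedule[i] * self.cea_test
            + self.ct_schedule[i] * self.ct_scan
        )

    def colonoscopy_cost(self, cycle: int) -> float:
        return float(self.colonoscopy_schedule[cycle - 1]) * self.colonoscopy

    def indirect_remission(self, cycle: int) -> float:
        return self.indirect_remission_annual if cycle <= self.indirect_years else 0.0

    def indirect_recurrence(self, cycle: int) -> float:
        return self.indirect_recurrence_annual if cycle <= self.indirect_years else 0.0


# ---------------------------------------------------------------------------
# ICER / dominance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-person totals for one treatment strategy."""

    name: str
    cost: float
    qaly: float
    ly: float = math.nan


@dataclass(frozen=True)
class Comparison:
    """Pairwise deltas of a strategy versus the reference (strategy - reference)."""

    name: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_qaly: float  # NaN when delta_qaly == 0
    icer_ly: float
    classification: str  # dominated | dominant | icer_reported | equivalent | icer_undefined


@dataclass(frozen=True)
class CeResult:
    reference: str
    strategies: tuple[StrategyResult, ...]
    comparisons: tuple[Comparison, ...]

    def comparison(self, name: str) -> Comparison:
        return next(c for c in self.comparisons if c.name == name)

    def classification(self, name: str) -> str:
        return self.comparison(name).classification


def _classify(delta_cost: float, delta_effect: float) -> str:
    if delta_effect == 0:
        return "equivalent" if delta_cost == 0 else "icer_undefined"
    if delta_cost > 0 and delta_effect < 0:
        return "dominated"
    if delta_cost < 0 and delta_effect > 0:
        return "dominant"
    return "icer_reported"


def compute_icer(results: Sequence[StrategyResult], reference: str) -> CeResult:
    """Pairwise ICERs and dominance classification versus a reference strategy.

    A comparator is *dominated* when it is both more costly and less
    effective than the reference; the (negative) ratio is still reported,
    parenthetically, as is conventional in base-case tables.
    """
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names: {names}")
    if len(results) < 2:
        raise ValueError("at least two strategies required")
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among strategies {names}")
    by_name = {r.name: r for r in results}
    ref = by_name[reference]
    comparisons = []
    for r in sorted(results, key=lambda r: r.name):
        if r.name == reference:
            continue
        dc = r.cost - ref.cost
        dq = r.qaly - ref.qaly
        dl = r.ly - ref.ly
        comparisons.append(
            Comparison(
                name=r.name,
                delta_cost=dc,
                delta_qaly=dq,
                delta_ly=dl,
                icer_qaly=dc / dq if dq != 0 else math.nan,
                icer_ly=dc / dl if dl != 0 else math.nan,
                classification=_classify(dc, dq),
            )
        )
    ordered = tuple(sorted(results, key=lambda r: r.name))
    return CeResult(reference=reference, strategies=ordered, comparisons=tuple(comparisons))


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """``wtp * QALY - cost``; linearizes the cost-effectiveness decision rule."""
    return wtp * result.qaly - result.cost


def dominance_frontier(results: Sequence[StrategyResult]) -> dict[str, str]:
    """Full dominance analysis including extended dominance.

    Classifies each strategy as ``frontier``, ``dominated`` (strict) or
    ``extended_dominated`` (removed because a blend of cheaper and more
    expensive frontier strategies delivers more QALYs at the same cost,
    i.e. ICERs along the cost-sorted frontier must be increasing).
    """
    status = {r.name: "frontier" for r in results}
    pool = sorted(results, key=lambda r: (r.cost, -r.qaly))
    # strict dominance
    for r in results:
        if any(
            (o.cost <= r.cost and o.qaly > r.qaly)
            or (o.cost < r.cost and o.qaly >= r.qaly)
            for o in results
        ):
            status[r.name] = "dominated"
    # extended dominance on the survivors
    survivors = [r for r in pool if status[r.name] == "frontier"]
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            lo, mid, hi = survivors[i - 1], survivors[i], survivors[i + 1]
            icer_lo = (mid.cost - lo.cost) / (mid.qaly - lo.qaly)
            icer_hi = (hi.cost - mid.cost) / (hi.qaly - mid.qaly)
            if icer_lo >= icer_hi:
                status[mid.name] = "extended_dominated"
                survivors.pop(i)
                changed = True
                break
    return status


def ce_table(result: CeResult) -> pd.DataFrame:
    """Base-case report layout: one column per strategy, reference first."""
    cols = [result.reference] + [c.name for c in result.comparisons]
    by_name = {r.name: r for r in result.strategies}
    comp = {c.name: c for c in result.comparisons}
    rows: dict[str, list] = {
        "total_cost": [],
        "delta_cost": [],
        "total_qaly": [],
        "delta_qaly": [],
        "icer_qaly": [],
        "total_ly": [],
        "delta_ly": [],
        "icer_ly": [],
        "classification": [],
    }
    for name in cols:
        r = by_name[name]
        c = comp.get(name)
        rows["total_cost"].append(r.cost)
        rows["total_qaly"].append(r.qaly)
        rows["total_ly"].append(r.ly)
        rows["delta_cost"].append(c.delta_cost if c else math.nan)
        rows["delta_qaly"].append(c.delta_qaly if c else math.nan)
        rows["delta_ly"].append(c.delta_ly if c else math.nan)
        rows["icer_qaly"].append(c.icer_qaly if c else math.nan)
        rows["icer_ly"].append(c.icer_ly if c else math.nan)
        rows["classification"].append(c.classification if c else "reference")
    return pd.DataFrame(rows, index=pd.Index(cols, name="strategy")).T
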