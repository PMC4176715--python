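"""Sensitivity analyses: one-way / tornado, threshold scanning, and
probabilistic sensitivity analysis (PSA) with cost-effectiveness
acceptability curves (CEAC).

One-way analyses report the incremental net monetary benefit (NMB) of
aspirin versus its best comparator at the willingness-to-pay threshold;
unlike the ICER, the NMB stays well-defined under dominance.  Parameters
address the model bundle through dotted paths
(``strategies.aspirin.rr_progression``, ``costs.metastatic_annual``, ...);
age-dependent schedules are varied by a single scalar that rescales the
whole profile, preserving its shape.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd

from .crc_models import ModelBundle
from .economics import net_monetary_benefit

__all__ = [
    "Beta",
    "Gamma",
    "LogNormal",
    "Uniform",
    "Degenerate",
    "lognormal_from_rr_ci",
    "beta_from_mean_sd",
    "gamma_from_mean_sd",
    "ParameterSpec",
    "TornadoEntry",
    "one_way",
    "tornado",
    "ThresholdCrossing",
    "threshold_scan",
    "scan_parameter",
    "PsaResult",
    "run_psa",
    "ceac",
]

#: tornado spread above which a parameter is flagged as highly uncertain
#: and fed into the PSA parameter set
HIGH_UNCERTAINTY_SPREAD = 50_000.0


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Beta:
    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be > 0")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class Gamma:
    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma parameters must be > 0")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))


@dataclass(frozen=True)
class LogNormal:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    def sample(self, rng: np.random.Generator) -> float:
        if self.sigma == 0:
            return math.exp(self.mu)
        return float(rng.lognormal(self.mu, self.sigma))


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if self.high < self.low:
            raise ValueError("high must be >= low")

    @property
    def mean(self) -> float:
        return (self.low + self.high) / 2

    @property
    def sd(self) -> float:
        return (self.high - self.low) / math.sqrt(12)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class Degenerate:
    """Point mass; PSA draws reproduce the base case exactly."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator) -> float:
        return self.value


Distribution = Beta | Gamma | LogNormal | Uniform | Degenerate


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


def lognormal_from_rr_ci(rr: float, lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal relative risk from its 95% CI.

    ``mu = ln rr``; ``sigma = (ln hi - ln lo) / (2 * 1.96)``.
    """
    if not (0 < lo <= rr <= hi):
        raise ValueError(f"need 0 < lo <= rr <= hi, got ({rr}, {lo}, {hi})")
    return math.log(rr), (math.log(hi) - math.log(lo)) / (2 * 1.959963984540054)


def beta_from_mean_sd(mean: float, sd: float) -> Beta:
    """Moment-matched Beta distribution from mean and standard deviation."""
    if not 0 < mean < 1:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if sd**2 >= mean * (1 - mean):
        raise ValueError(
            f"infeasible: sd^2 = {sd**2:.3g} must be < mean(1-mean) = "
            f"{mean * (1 - mean):.3g}"
        )
    nu = mean * (1 - mean) / sd**2 - 1
    return Beta(alpha=mean * nu, beta=(1 - mean) * nu)


def gamma_from_mean_sd(mean: float, sd: float) -> Gamma:
    """Moment-matched Gamma distribution (shape/scale) from mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    return Gamma(shape=(mean / sd) ** 2, scale=sd**2 / mean)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _resolve(bundle: ModelBundle, path: str):
    """Return (owner object, final attribute name) for a dotted path."""
    parts = path.split(".")
    obj = bundle
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj, parts[-1]


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input.

    ``kind == "scalar"`` sets the target attribute to the value directly;
    ``kind == "profile"`` treats the target as a per-cycle array and
    rescales it by ``value / base`` (``base`` being the profile's largest
    base-case entry, per the convention that ranges of time-varying inputs
    refer to their largest value).
    """

    name: str
    base: float
    low: float
    high: float
    target: str
    distribution: Distribution | None = None
    kind: str = "scalar"  # scalar | profile
    is_cost: bool = False
    in_psa: bool = False

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.kind not in ("scalar", "profile"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "profile" and self.base <= 0:
            raise ValueError(f"{self.name}: profile base must be > 0")

    def apply(self, bundle: ModelBundle, value: float) -> ModelBundle:
        """Return a deep copy of the bundle with this parameter set."""
        new = copy.deepcopy(bundle)
        self.apply_inplace(new, value)
        return new

    def apply_inplace(self, bundle: ModelBundle, value: float) -> None:
        owner, attr = _resolve(bundle, self.target)
        if self.kind == "scalar":
            setattr(owner, attr, value)
        else:
            profile = np.asarray(getattr(owner, attr), dtype=float)
            setattr(owner, attr, profile * (value / self.base))


# ---------------------------------------------------------------------------
# One-way sensitivity analysis / tornado
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    outcome_low: float  # incremental NMB at the parameter's low end
    outcome_high: float
    high_uncertainty: bool = False

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def incremental_nmb(bundle: ModelBundle, focal: str = "aspirin") -> float:
    """NMB of the focal strategy minus the best comparator's NMB."""
    outcomes = bundle.run()
    wtp = bundle.config.wtp
    nmb = {name: net_monetary_benefit(o.result, wtp) for name, o in outcomes.items()}
    others = [v for k, v in nmb.items() if k != focal]
    if not others:
        raise ValueError("incremental NMB needs at least one comparator")
    return nmb[focal] - max(others)


def one_way(
    param: ParameterSpec,
    bundle: ModelBundle,
    outcome: Callable[[ModelBundle], float] | None = None,
) -> TornadoEntry:
    """Outcome at the parameter's range ends, all other inputs at base."""
    f = outcome or incremental_nmb
    lo = f(param.apply(bundle, param.low))
    hi = f(param.apply(bundle, param.high))
    entry = TornadoEntry(parameter=param.name, outcome_low=lo, outcome_high=hi)
    return replace(entry, high_uncertainty=entry.spread > HIGH_UNCERTAINTY_SPREAD)


def tornado(
    params: Sequence[ParameterSpec],
    bundle: ModelBundle,
    outcome: Callable[[ModelBundle], float] | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every parameter, sorted by descending spread."""
    if not params:
        raise ValueError("at least one parameter required")
    entries = [one_way(p, bundle, outcome) for p in params]
    return sorted(entries, key=lambda e: -e.spread)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "outcome_low": [e.outcome_low for e in entries],
            "outcome_high": [e.outcome_high for e in entries],
            "spread": [e.spread for e in entries],
            "high_uncertainty": [e.high_uncertainty for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Threshold (break-even) scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdCrossing:
    value: float
    label_below: Hashable
    label_above: Hashable


def threshold_scan(
    classify: Callable[[float], Hashable],
    lo: float,
    hi: float,
    n_grid: int = 101,
    xtol: float = 1e-4,
) -> list[ThresholdCrossing]:
    """Locate every value where a discrete classification changes.

    A grid pre-scan (``n_grid`` >= 100 points recommended) brackets each
    change, then bisection narrows it to ``xtol``.  Multiple crossings are
    all returned (callers should treat more than one as a non-monotone
    response worth inspecting).  Empty list = no change over the range.
    """
    if hi <= lo:
        raise ValueError("need hi > lo")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    grid = np.linspace(lo, hi, n_grid)
    labels = [classify(float(x)) for x in grid]
    crossings: list[ThresholdCrossing] = []
    for i in range(len(grid) - 1):
        if labels[i] == labels[i + 1]:
            continue
        a, b = float(grid[i]), float(grid[i + 1])
        la, lb = labels[i], labels[i + 1]
        while b - a > xtol:
            mid = (a + b) / 2
            lm = classify(mid)
            if lm == la:
                a = mid
            else:
                b, lb = mid, lm
        crossings.append(
            ThresholdCrossing(value=(a + b) / 2, label_below=la, label_above=lb)
        )
    return crossings


def scan_parameter(
    param: ParameterSpec,
    bundle: ModelBundle,
    lo: float | None = None,
    hi: float | None = None,
    reference: str = "aspirin",
    comparator: str | None = None,
    n_grid: int = 101,
    xtol: float | None = None,
) -> list[ThresholdCrossing]:
    """Scan one model parameter for dominance-classification changes.

    The classification label is the tuple of pairwise classifications of
    every comparator versus the reference arm (or of a single named
    comparator).  Tolerance defaults to 1e-4 for probabilities, utilities
    and relative risks and to 1 USD for costs.
    """
    lo = param.low if lo is None else lo
    hi = param.high if hi is None else hi
    if xtol is None:
        xtol = 1.0 if param.is_cost else 1e-4

    def classify(value: float) -> Hashable:
        ce = param.apply(bundle, value).ce_result(reference=reference)
        if comparator is not None:
            return ce.classification(comparator)
        return tuple(c.classification for c in ce.comparisons)

    return threshold_scan(classify, lo, hi, n_grid=n_grid, xtol=xtol)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo PSA output.

    ``samples``: tidy frame (iteration, strategy, cost, qaly);
    ``draws``: one row per iteration with every sampled parameter value;
    ``n_clamped``: count of draws clamped into their valid domain
    (e.g. a rescaled probability profile exceeding 1).
    """

    samples: pd.DataFrame
    draws: pd.DataFrame
    n_clamped: int


def run_psa(
    params: Sequence[ParameterSpec],
    bundle: ModelBundle,
    n_iter: int,
    seed: int,
) -> PsaResult:
    """Monte-Carlo PSA: joint independent draws, model rebuilt per iteration.

    Iteration ``i`` uses the generator ``default_rng([seed, i])``, so any
    subset of iterations is reproducible independently of execution order.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for p in params:
        if p.distribution is None:
            raise ValueError(f"parameter {p.name} has no distribution")
    records = []
    draw_rows = []
    n_clamped = 0
    for i in range(n_iter):
        rng = np.random.default_rng([seed, i])
        current = copy.deepcopy(bundle)
        row = {"iteration": i}
        for p in params:
            value = p.distribution.sample(rng)
            if p.kind == "profile":
                # keep the rescaled probability profile inside [0, 1]
                owner, attr = _resolve(current, p.target)
                profile = np.asarray(getattr(owner, attr), dtype=float)
                scaled = profile * (value / p.base)
                if attr.startswith("p_") and (scaled > 1).any():
                    scaled = np.minimum(scaled, 1.0)
                    n_clamped += 1
                setattr(owner, attr, scaled)
            else:
                if p.target.split(".")[-1].startswith(("p_", "pill")) and value > 1:
                    value = 1.0
                    n_clamped += 1
                p.apply_inplace(current, value)
            row[p.name] = value
        draw_rows.append(row)
        for name, outcome in current.run().items():
            records.append(
                {
                    "iteration": i,
                    "strategy": name,
                    "cost": outcome.totals.cost,
                    "qaly": outcome.totals.qaly,
                }
            )
    return PsaResult(
        samples=pd.DataFrame.from_records(records),
        draws=pd.DataFrame.from_records(draw_rows),
        n_clamped=n_clamped,
    )


def ceac(samples: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value the winning strategy of an iteration
    maximizes net monetary benefit ``wtp * qaly - cost``; ties break to the
    lexicographically first strategy name.  Returns a tidy frame
    (wtp, strategy, fraction); fractions sum to 1 at every wtp.
    """
    if samples.empty:
        raise ValueError("PSA samples are empty")
    wide_c = samples.pivot(index="iteration", columns="strategy", values="cost")
    wide_q = samples.pivot(index="iteration", columns="strategy", values="qaly")
    strategies = sorted(wide_c.columns)  # lexicographic tie-break via argmax order
    cost = wide_c[strategies].to_numpy()
    qaly = wide_q[strategies].to_numpy()
    n_iter = cost.shape[0]
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * qaly - cost
        winners = nmb.argmax(axis=1)  # first maximum = lexicographic tie-break
        counts = np.bincount(winners, minlength=len(strategies))
        for j, name in enumerate(strategies):
            rows.append(
                {"wtp": float(wtp), "strategy": name, "fraction": counts[j] / n_iter}
            )
    return pd.DataFrame(rows)
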