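"""Packaged model inputs: loading the declarative per-stage configuration.

The shipped ``data/model_inputs.yaml`` carries every point estimate,
sensitivity range and PSA distribution of the two stage models; this
module turns it (or a user-supplied file with the same schema, see
``data/config.schema.json``) into the dataclasses the pipeline consumes.

Age-dependent aspirin bleeding inputs are linear interpolations between
their age-65 and age-85 values; the weighted episode costs are rederived
per age from the event-level probabilities and unit charges via
:func:`crcea.economics.weighted_ae_cost`, so the cost fixtures stay
consistent with their stated derivation.
"""

from __future__ import annotations

import functools
import importlib.resources
from pathlib import Path

import numpy as np
import yaml

from .crc_models import ModelBundle, ModelConfig, NaturalHistory, StrategySpec, UtilityInputs
from .economics import (
    CPI_MEDICAL_2013,
    CostInputs,
    CostItem,
    weighted_ae_cost,
)
from .model_core import DiscountSpec
from .sensitivity import (
    Beta,
    Gamma,
    LogNormal,
    ParameterSpec,
    Uniform,
    beta_from_mean_sd,
    gamma_from_mean_sd,
    lognormal_from_rr_ci,
)

__all__ = [
    "load_inputs",
    "stage_config",
    "cost_items",
    "cost_inputs",
    "utility_inputs",
    "strategy_specs",
    "parameter_specs",
    "model_config",
    "default_bundle",
    "fixture_tables",
]

STAGES = ("I", "II")


def _data_path() -> Path:
    return Path(str(importlib.resources.files("crcea").joinpath("data")))


@functools.lru_cache(maxsize=8)
def load_inputs(path: str | None = None) -> dict:
    """Parse the model-inputs document (packaged file by default)."""
    p = Path(path) if path else _data_path() / "model_inputs.yaml"
    with open(p) as fh:
        return yaml.safe_load(fh)


def stage_config(stage: str, path: str | None = None) -> dict:
    """Common block merged with the per-stage block."""
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    doc = load_inputs(path)
    merged = dict(doc["common"])
    merged.update(doc[f"stage_{stage}"])
    merged["stage"] = stage
    return merged


def _age_profile(p65: float, p85: float, start_age: int, horizon: int) -> np.ndarray:
    """Linear interpolation over start-of-cycle ages 65..85."""
    ages = start_age + np.arange(horizon)
    return p65 + (ages - 65) / 20.0 * (p85 - p65)


def model_config(stage: str, path: str | None = None) -> ModelConfig:
    cfg = stage_config(stage, path)
    return ModelConfig(
        stage=stage,
        start_age=cfg["start_age"],
        horizon=cfg["horizon"],
        cohort_size=float(cfg["cohort_size"]),
        discount=DiscountSpec(**cfg["discount"]),
        wtp=float(cfg["wtp"]),
    )


def cost_items(stage: str = "I", path: str | None = None) -> list[CostItem]:
    """Audit-grade cost-item table (raw amount, source year, printed value)."""
    cfg = stage_config(stage, path)
    items = []
    for name, spec in cfg["cost_items"].items():
        items.append(
            CostItem(
                name=name,
                raw_amount=float(spec["raw"]),
                source_year=int(spec["year"]),
                unit=spec.get("unit", "per_year"),
                months=int(spec.get("months", 1)),
                printed_2013=spec.get("printed"),
                note=spec.get("note", ""),
            )
        )
    return items


def _item_value(cfg: dict, name: str) -> float:
    spec = cfg["cost_items"][name]
    item = CostItem(
        name=name,
        raw_amount=float(spec["raw"]),
        source_year=int(spec["year"]),
        unit=spec.get("unit", "per_year"),
        months=int(spec.get("months", 1)),
        printed_2013=spec.get("printed"),
    )
    return item.value_2013()


def cost_inputs(stage: str, path: str | None = None) -> CostInputs:
    cfg = stage_config(stage, path)
    sched = cfg["surveillance_schedules"]
    horizon = cfg["horizon"]
    colonoscopy_schedule = np.zeros(horizon)
    for year in sched["colonoscopy_years"]:
        if year <= horizon:
            colonoscopy_schedule[year - 1] = 1.0
    return CostInputs(
        physician_visit=_item_value(cfg, "physician_visit"),
        blood_test=_item_value(cfg, "blood_test"),
        cea_test=_item_value(cfg, "cea_test"),
        ct_scan=_item_value(cfg, "ct_scan"),
        colonoscopy=_item_value(cfg, "colonoscopy"),
        metastatic_annual=_item_value(cfg, "metastatic_annual"),
        indirect_remission_annual=_item_value(cfg, "indirect_remission_annual"),
        indirect_recurrence_annual=_item_value(cfg, "indirect_recurrence_annual"),
        visit_schedule=np.asarray(sched["physician_visits_per_year"], dtype=float),
        blood_schedule=np.asarray(sched["blood_tests_per_year"], dtype=float),
        cea_schedule=np.asarray(sched["cea_tests_per_year"], dtype=float),
        ct_schedule=np.asarray(sched["ct_scans_per_year"], dtype=float),
        colonoscopy_schedule=colonoscopy_schedule,
        indirect_years=int(cfg["indirect_cost_years"]),
    )


def utility_inputs(stage: str, path: str | None = None) -> UtilityInputs:
    cfg = stage_config(stage, path)
    u = cfg["utilities"]
    return UtilityInputs(
        remission_intervention=u["remission_intervention"]["value"],
        remission_discontinued=u["remission_discontinued"]["value"],
        recurrence=u["recurrence"]["value"],
    )


def aspirin_ae_cost_profiles(
    stage: str = "I", path: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(non-fatal, fatal) weighted episode-cost profiles per cycle, 2013 USD."""
    cfg = stage_config(stage, path)
    start_age, horizon = cfg["start_age"], cfg["horizon"]
    cpi = {int(k): v for k, v in cfg["cpi_medical_2013"].items()}
    out = []
    for kind in ("nonfatal", "fatal"):
        events = cfg["aspirin_ae_events"][kind]
        profile = np.empty(horizon)
        for i in range(horizon):
            probs, costs, factors = [], [], []
            for ev in events.values():
                probs.append(
                    _age_profile(ev["p65"], ev["p85"], start_age, horizon)[i]
                )
                costs.append(ev["cost"])
                factors.append(cpi[int(ev["year"])])
            # single source year per event set
            profile[i] = weighted_ae_cost(probs, costs, cpi_factor=factors[0])
        out.append(profile)
    return out[0], out[1]


def strategy_specs(stage: str, path: str | None = None) -> dict[str, StrategySpec]:
    cfg = stage_config(stage, path)
    start_age, horizon = cfg["start_age"], cfg["horizon"]
    specs: dict[str, StrategySpec] = {}
    for name in cfg["strategies"] if isinstance(cfg["strategies"], list) else []:
        raw = load_inputs(path)["common"]["strategies"][name]
        if name == "no_treatment":
            specs[name] = StrategySpec.no_treatment(horizon)
        elif name == "aspirin":
            ae_nonfatal, ae_fatal = aspirin_ae_cost_profiles(stage, path)
            treatment_years = raw["treatment_years"]
            drug = np.zeros(horizon)
            drug[:treatment_years] = raw["drug_cost_annual"]
            specs[name] = StrategySpec(
                name=name,
                horizon=horizon,
                rr_progression=raw["rr_progression"],
                benefit_years=raw["benefit_years"],
                treatment_years=treatment_years,
                pill_utility=raw["pill_utility"],
                p_fatal_ae=_age_profile(
                    raw["p_fatal_ae"]["age_profile"]["p65"],
                    raw["p_fatal_ae"]["age_profile"]["p85"],
                    start_age,
                    horizon,
                ),
                p_nonfatal_ae=_age_profile(
                    raw["p_nonfatal_ae"]["age_profile"]["p65"],
                    raw["p_nonfatal_ae"]["age_profile"]["p85"],
                    start_age,
                    horizon,
                ),
                drug_cost=drug,
                ae_nonfatal_cost=ae_nonfatal,
                ae_fatal_cost=ae_fatal,
            )
        elif name == "capecitabine":
            first = np.zeros(horizon)
            first[0] = 1.0
            specs[name] = StrategySpec(
                name=name,
                horizon=horizon,
                rr_progression=raw["rr_progression"],
                benefit_years=raw["benefit_years"],
                treatment_years=raw["treatment_years"],
                p_fatal_ae=first * raw["p_fatal_ae"]["first_year"],
                p_nonfatal_ae=first * raw["p_nonfatal_ae"]["first_year"],
                drug_cost=first * raw["drug_cost_first_year"],
                ae_nonfatal_cost=first * raw["ae_nonfatal_cost_year"],
                ae_fatal_cost=first * raw["ae_fatal_cost_episode"],
                extra_visits=first * raw["extra_visits_first_year"],
            )
        else:
            raise ValueError(f"unknown strategy {name!r} in configuration")
    return specs


def _utility_psa(spec: dict):
    psa = spec.get("psa")
    if psa is None:
        return None
    return beta_from_mean_sd(psa["mean"], psa["sd"])


def parameter_specs(stage: str, path: str | None = None) -> list[ParameterSpec]:
    """One-way SA parameter set with PSA distributions where assigned."""
    cfg = stage_config(stage, path)
    common = load_inputs(path)["common"]
    psa_set = set(cfg.get("psa_parameters", []))
    asp = common["strategies"]["aspirin"]
    params: list[ParameterSpec] = []

    mu, sigma = lognormal_from_rr_ci(asp["rr_progression"], *asp["rr_ci95"])
    params.append(
        ParameterSpec(
            name="rr_aspirin",
            base=asp["rr_progression"],
            low=asp["rr_ci95"][0],
            high=asp["rr_ci95"][1],
            target="strategies.aspirin.rr_progression",
            distribution=LogNormal(mu, sigma),
            in_psa="rr_aspirin" in psa_set,
        )
    )
    for label in ("p_fatal_ae", "p_nonfatal_ae"):
        prof = asp[label]["age_profile"]
        p65, p85 = prof["p65"], prof["p85"]
        # Ranges of time-varying inputs refer to their largest value, so the
        # scaling base is the age-85 endpoint.  The PSA uniform draws the
        # whole profile (shape preserved) so that its *mean* annual
        # probability spans the printed age band [p65, p85]; expressed on
        # the largest-value scale that band becomes
        # [p65, p85] * p85 / mean(profile), centred on the base profile.
        p_mean = (p65 + p85) / 2
        params.append(
            ParameterSpec(
                name=f"{label}_aspirin",
                base=p85,
                low=asp[label]["sa_range"][0],
                high=asp[label]["sa_range"][1],
                target=f"strategies.aspirin.{label}",
                distribution=Uniform(p65 * p85 / p_mean, p85 * p85 / p_mean),
                kind="profile",
                in_psa=f"{label}_aspirin" in psa_set,
            )
        )
    psa = asp["pill_utility_psa"]
    params.append(
        ParameterSpec(
            name="u_aspirin",
            base=asp["pill_utility"],
            low=asp["pill_utility_range"][0],
            high=asp["pill_utility_range"][1],
            target="strategies.aspirin.pill_utility",
            distribution=beta_from_mean_sd(psa["mean"], psa["sd"]),
            in_psa="u_aspirin" in psa_set,
        )
    )
    params.append(
        ParameterSpec(
            name="drug_cost_aspirin",
            base=asp["drug_cost_annual"],
            low=asp["drug_cost_range"][0],
            high=asp["drug_cost_range"][1],
            target="strategies.aspirin.drug_cost",
            kind="profile",
            is_cost=True,
            in_psa=False,
        )
    )
    # weighted AE episode costs, +/-20% on the profile
    frac_lo, frac_hi = common["ae_cost_sa_fraction"]
    ae_nonfatal, ae_fatal = aspirin_ae_cost_profiles(stage, path)
    for label, profile in (("nonfatal", ae_nonfatal), ("fatal", ae_fatal)):
        base = float(profile.max())
        params.append(
            ParameterSpec(
                name=f"ae_cost_{label}_aspirin",
                base=base,
                low=frac_lo * base,
                high=frac_hi * base,
                target=f"strategies.aspirin.ae_{label}_cost",
                kind="profile",
                is_cost=True,
                in_psa=False,
            )
        )

    for key, uspec in cfg["utilities"].items():
        params.append(
            ParameterSpec(
                name=f"u_{key}",
                base=uspec["value"],
                low=uspec["sa_range"][0],
                high=uspec["sa_range"][1],
                target=f"utilities.{key}",
                distribution=_utility_psa(uspec),
                in_psa=f"u_{key}" in psa_set,
            )
        )

    met_psa = common["metastatic_psa"]
    params.append(
        ParameterSpec(
            name="metastatic_cost",
            base=_item_value(cfg, "metastatic_annual"),
            low=common["metastatic_sa_range"][0],
            high=common["metastatic_sa_range"][1],
            target="costs.metastatic_annual",
            distribution=gamma_from_mean_sd(met_psa["mean"], met_psa["sd"]),
            is_cost=True,
            in_psa="metastatic_cost" in psa_set,
        )
    )
    for name, attr, rng_key in (
        ("indirect_remission", "costs.indirect_remission_annual", "indirect_remission_range"),
        ("indirect_recurrence", "costs.indirect_recurrence_annual", "indirect_recurrence_range"),
    ):
        base = _item_value(cfg, f"{name}_annual")
        params.append(
            ParameterSpec(
                name=name,
                base=base,
                low=common[rng_key][0],
                high=common[rng_key][1],
                target=attr,
                is_cost=True,
                in_psa=False,
            )
        )

    if "capecitabine" in cfg["strategies"]:
        cape = common["strategies"]["capecitabine"]
        mu, sigma = lognormal_from_rr_ci(cape["rr_progression"], *cape["rr_ci95"])
        cape_params = [
            ParameterSpec(
                name="rr_capecitabine",
                base=cape["rr_progression"],
                low=cape["rr_ci95"][0],
                high=cape["rr_ci95"][1],
                target="strategies.capecitabine.rr_progression",
                distribution=LogNormal(mu, sigma),
                in_psa="rr_capecitabine" in psa_set,
            ),
            ParameterSpec(
                name="p_fatal_ae_capecitabine",
                base=cape["p_fatal_ae"]["first_year"],
                low=cape["p_fatal_ae"]["sa_range"][0],
                high=cape["p_fatal_ae"]["sa_range"][1],
                target="strategies.capecitabine.p_fatal_ae",
                distribution=Beta(
                    cape["p_fatal_ae_psa"]["alpha"], cape["p_fatal_ae_psa"]["beta"]
                ),
                kind="profile",
                in_psa="p_fatal_ae_capecitabine" in psa_set,
            ),
            ParameterSpec(
                name="p_nonfatal_ae_capecitabine",
                base=cape["p_nonfatal_ae"]["first_year"],
                low=cape["p_nonfatal_ae"]["sa_range"][0],
                high=cape["p_nonfatal_ae"]["sa_range"][1],
                target="strategies.capecitabine.p_nonfatal_ae",
                kind="profile",
                in_psa=False,
            ),
            ParameterSpec(
                name="drug_cost_capecitabine",
                base=cape["drug_cost_first_year"],
                low=cape["drug_cost_range"][0],
                high=cape["drug_cost_range"][1],
                target="strategies.capecitabine.drug_cost",
                distribution=gamma_from_mean_sd(
                    cape["drug_cost_psa"]["mean"], cape["drug_cost_psa"]["sd"]
                ),
                kind="profile",
                is_cost=True,
                in_psa="drug_cost_capecitabine" in psa_set,
            ),
            ParameterSpec(
                name="ae_cost_nonfatal_capecitabine",
                base=cape["ae_nonfatal_cost_year"],
                low=cape["ae_nonfatal_cost_range"][0],
                high=cape["ae_nonfatal_cost_range"][1],
                target="strategies.capecitabine.ae_nonfatal_cost",
                kind="profile",
                is_cost=True,
                in_psa=False,
            ),
            ParameterSpec(
                name="ae_cost_fatal_capecitabine",
                base=cape["ae_fatal_cost_episode"],
                low=cape["ae_fatal_cost_range"][0],
                high=cape["ae_fatal_cost_range"][1],
                target="strategies.capecitabine.ae_fatal_cost",
                kind="profile",
                is_cost=True,
                in_psa=False,
            ),
        ]
        params.extend(cape_params)
    return params


def default_bundle(
    stage: str,
    nh: NaturalHistory | None = None,
    path: str | None = None,
) -> ModelBundle:
    """Fully assembled stage model with the packaged inputs.

    ``nh`` defaults to the synthetic natural history for the stage; a
    registry-derived table loaded from CSV drops in here.
    """
    from .synthetic_data import DEFAULT_PARAMS, generate_natural_history

    if nh is None:
        nh = generate_natural_history(DEFAULT_PARAMS[stage])
    return ModelBundle(
        config=model_config(stage, path),
        nh=nh,
        strategies=strategy_specs(stage, path),
        costs=cost_inputs(stage, path),
        utilities=utility_inputs(stage, path),
    )


def fixture_tables(stage: str = "I", path: str | None = None):
    """(CostInputs, UtilityInputs, strategies, ParameterSpec list) for a stage."""
    return (
        cost_inputs(stage, path),
        utility_inputs(stage, path),
        strategy_specs(stage, path),
        parameter_specs(stage, path),
    )
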