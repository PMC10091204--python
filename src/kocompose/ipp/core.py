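"""Library-level implementations of the composite's submodel computations.

These are the same computations the generated KO payloads perform — both
delegate the arithmetic to :mod:`kocompose.ipp.formulas`, so results agree
bit-for-bit between the direct (in-process) path and the gateway path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

from kocompose.ipp import formulas
from kocompose.ipp.catalog import ServiceDefinition
from kocompose.ipp.lifetable import MortalitySchedule

__all__ = [
    "MissingFeatureError",
    "ServiceBenefit",
    "derive_features",
    "adjust_mortality",
    "life_expectancy",
    "life_gain",
    "net_benefit",
    "detection_gain",
    "diet_risk",
    "background_risk",
    "rank_services",
]


class MissingFeatureError(KeyError):
    """A computation needed a patient feature that is absent."""

    def __init__(self, feature: str):
        super().__init__(feature)
        self.feature = feature

    def __str__(self) -> str:
        return f"required patient feature {self.feature!r} is missing"


@dataclass(frozen=True)
class ServiceBenefit:
    """Per-service estimated marginal life gain in years."""

    code: str
    life_gain: float


def derive_features(features: Mapping[str, Any], cvd_score_params: dict) -> dict:
    """Extend a feature record with the five derived quantities.

    Adds BMI, body surface area (Mosteller), cardiac output, creatinine
    clearance (Cockcroft-Gault), and a synthetic logistic cardiovascular risk
    score. A derivation whose inputs are absent is simply skipped; the others
    are still computed.
    """
    out = formulas.add_bmi(features)
    out = formulas.add_bsa(out)
    out = formulas.add_cardiac_output(out)
    out = formulas.add_creatinine_clearance(out)
    out = formulas.add_cvd_risk(
        out, cvd_score_params["intercept"], cvd_score_params["coefficients"]
    )
    return out


def adjust_mortality(
    sched: MortalitySchedule,
    features: Mapping[str, Any],
    adjustments: Mapping[str, dict],
) -> MortalitySchedule:
    """Scale a schedule by each behavioural relative risk in turn, capping at 1.

    Factors apply sequentially (obesity, alcohol, tobacco in the default
    configuration); with all relative risks >= 1 the sequential product
    equals the one-shot product q * RR_o * RR_a * RR_t capped at 1.
    """
    rates = list(sched.rates)
    for spec in adjustments.values():
        rr = formulas.behaviour_rr(features, spec)
        rates = formulas.scale_hazards(rates, rr)
    return MortalitySchedule(start_age=sched.start_age, rates=tuple(rates))


def life_expectancy(sched: MortalitySchedule | list[float] | tuple[float, ...]) -> float:
    """Expected whole years lived; discrete survival sum, no half-year correction."""
    rates = sched.rates if isinstance(sched, MortalitySchedule) else sched
    return formulas.survival_life_expectancy(list(rates))


def life_gain(le_with: float, le_without: float) -> float:
    return formulas.expectancy_difference(le_with, le_without)


def net_benefit(service: ServiceDefinition, sched: MortalitySchedule) -> ServiceBenefit:
    """Marginal life gain from scaling all-cause hazards by the service's ratio."""
    if service.hr is None or not (0.0 < service.hr <= 1.0):
        raise ValueError(f"service {service.code}: hazard ratio must lie in (0, 1]")
    rates = list(sched.rates)
    treated = formulas.scale_hazards(rates, service.hr)
    gain = formulas.expectancy_difference(
        formulas.survival_life_expectancy(treated),
        formulas.survival_life_expectancy(rates),
    )
    return ServiceBenefit(code=service.code, life_gain=gain)


def detection_gain(service: ServiceDefinition, sched: MortalitySchedule) -> ServiceBenefit:
    """Expected life gain from detection: p_undiagnosed times the treated gain."""
    base = net_benefit(service, sched)
    return ServiceBenefit(code=service.code, life_gain=service.p_undiagnosed * base.life_gain)


def diet_risk(
    features: Mapping[str, Any], diet_params: Mapping[str, Any], baseline: float
) -> tuple[float, float]:
    """(relative risk, absolute risk) for diet adherence vs non-adherence.

    The relative risk is a two-level table on the adherence flag; absolute
    risk is baseline * RR capped at 1. The adherence feature must be present.
    """
    feature = diet_params["feature"]
    if feature not in features:
        raise MissingFeatureError(feature)
    rr = diet_params["adherent_rr"] if features[feature] else diet_params["nonadherent_rr"]
    absolute = min(1.0, baseline * rr)
    return rr, absolute


def background_risk(features: Mapping[str, Any], model: Mapping[str, Any]) -> float:
    """Background absolute probability from a logistic form over features."""
    return formulas.logistic(
        formulas.linear_score(features, model["coefficients"], model["intercept"])
    )


def rank_services(benefits: Mapping[str, float]) -> list[ServiceBenefit]:
    """Descending by life gain; ties break lexicographically by code."""
    ordered = sorted(benefits.items(), key=lambda kv: (-kv[1], kv[0]))
    return [ServiceBenefit(code=c, life_gain=g) for c, g in ordered]
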