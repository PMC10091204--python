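"""Run the preventive-services composite.

Two equivalent paths:

* :func:`run_cm_ipp` posts the patient record to the activated shelf's
  top-level executive through the gateway — the web-service path.
* :func:`run_direct` composes the same submodel computations in-process with
  no gateway — the embeddable library path, and the reference against which
  gateway transparency is tested. Both delegate all arithmetic to
  :mod:`kocompose.ipp.formulas`, so their outputs agree exactly.
"""

from __future__ import annotations

from typing import Any, Mapping

from kocompose.activator import Activator
from kocompose.ipp import formulas
from kocompose.ipp.catalog import load_catalog, load_params, eligible_services
from kocompose.ipp.codegen import REQUIRED_FEATURES
from kocompose.ipp.core import (
    adjust_mortality,
    background_risk,
    derive_features,
    detection_gain,
    diet_risk,
    net_benefit,
)
from kocompose.ipp.lifetable import MAX_AGE, LifeTable, mortality_schedule

__all__ = ["MissingFeaturesError", "GatewayError", "TOP_ENDPOINT", "run_cm_ipp", "run_direct"]

#: Endpoint key of the demo shelf's top-level executive.
TOP_ENDPOINT = "/ipp/ipp-executive/1.0/run"


class MissingFeaturesError(ValueError):
    """The patient record lacks required features; lists the missing keys."""

    def __init__(self, missing: list[str]):
        self.missing = sorted(missing)
        super().__init__("missing required features: " + ", ".join(self.missing))


class GatewayError(RuntimeError):
    """The gateway returned a non-ok status for a composite run."""

    def __init__(self, status: str, body: dict):
        self.status = status
        self.body = body
        super().__init__(f"gateway returned {status}: {body.get('error', body)}")


def _normalize(patient: Mapping[str, Any]) -> dict:
    """Accept a full record, a patient object, or bare features."""
    if "patient" in patient:
        record = dict(patient["patient"])
    elif "features" in patient:
        record = dict(patient)
    else:
        record = {"features": dict(patient)}
    record.setdefault("features", {})
    return record


def _check_required(features: Mapping[str, Any]) -> None:
    missing = [key for key in REQUIRED_FEATURES if key not in features]
    if missing:
        raise MissingFeaturesError(missing)


def run_cm_ipp(
    patient: Mapping[str, Any],
    activator: Activator,
    top_endpoint: str = TOP_ENDPOINT,
) -> dict:
    """Post a patient record to the activated shelf's top-level executive.

    Raises :class:`MissingFeaturesError` (listing the missing keys) before
    routing if the record is incomplete, and :class:`GatewayError` on any
    non-ok gateway status.
    """
    record = _normalize(patient)
    _check_required(record["features"])
    response = activator.route(top_endpoint, "post", {"patient": record})
    if response.status != "ok":
        raise GatewayError(response.status, response.body)
    return response.body["result"]


def run_direct(
    patient: Mapping[str, Any],
    life_table: LifeTable,
    params: dict | None = None,
) -> dict:
    """Run the composite in-process, no gateway: the reference composition."""
    if params is None:
        params = load_params()
    catalog = load_catalog(params)
    services = {s.code: s for s in catalog}
    record = _normalize(patient)
    features = dict(record["features"])
    _check_required(features)

    features = derive_features(features, params["cvd_risk_score"])
    eligible = eligible_services(features, catalog)
    age = int(features["age"])
    baseline = mortality_schedule(
        life_table, age, features["gender"], features["race"], MAX_AGE - age
    )
    adjusted_sched = adjust_mortality(baseline, features, params["adjustments"])
    rates = list(adjusted_sched.rates)
    baseline_le = formulas.survival_life_expectancy(rates)
    background = {
        name: background_risk(features, model)
        for name, model in params["background_models"].items()
        if name != "diet_disease"
    }

    gains: dict[str, float] = {}
    for code in eligible:
        service = services[code]
        if service.kind == "net_benefit":
            raw = net_benefit(service, adjusted_sched).life_gain
            scale = 1.0
            if service.background:
                scale = scale * background[service.background]
            if service.harm_background:
                scale = scale * (1.0 - background[service.harm_background])
            gains[code] = raw * scale
        elif service.kind == "detection":
            gains[code] = detection_gain(service, adjusted_sched).life_gain
        elif service.kind == "diet":
            diet_baseline = background_risk(
                features, params["background_models"]["diet_disease"]
            )
            rr, absolute = diet_risk(features, params["diet"], diet_baseline)
            treated = formulas.scale_hazards(rates, params["diet"]["adherent_rr"] / rr)
            le_with = formulas.survival_life_expectancy(treated)
            gain = formulas.expectancy_difference(le_with, baseline_le)
            gains[code] = absolute * gain
        elif service.kind == "inline_behavior":
            rr = formulas.behaviour_rr(features, params["adjustments"][service.behaviour])
            if rr <= 1.0:
                gains[code] = 0.0
            else:
                treated = formulas.scale_hazards(rates, 1.0 / rr)
                le_with = formulas.survival_life_expectancy(treated)
                gains[code] = formulas.expectancy_difference(le_with, baseline_le)
        else:  # inline_hr
            treated = formulas.scale_hazards(rates, service.hr)
            le_with = formulas.survival_life_expectancy(treated)
            gain = formulas.expectancy_difference(le_with, baseline_le)
            scale = 1.0
            if service.background:
                scale = scale * background[service.background]
            gains[code] = scale * gain

    ranked = sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "lifeexpectancy": {
            services[code].name: {"total": {"life-gain": gain}}
            for code, gain in gains.items()
        },
        "ranking": [code for code, _ in ranked],
    }
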