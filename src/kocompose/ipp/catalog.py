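"""Service catalog: definitions, parameters, and eligibility screening.

The catalog of 21 preventive services lives in ``params.yaml`` next to this
module. Each service carries a kind (which submodel estimates it), a
synthetic all-cause hazard ratio where applicable, optional links to
background-risk models, and an inclusion predicate over raw patient features
(age range, sex, flags, numeric bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

from kocompose.ipp import formulas

__all__ = [
    "ServiceDefinition",
    "load_params",
    "load_catalog",
    "eligible_services",
]

_VALID_KINDS = ("net_benefit", "detection", "diet", "inline_behavior", "inline_hr")


@dataclass(frozen=True)
class ServiceDefinition:
    """One preventive service: code, estimator kind, benefit parameters, criteria."""

    code: str
    name: str
    kind: str
    criteria: Mapping[str, Any]
    hr: float | None = None
    background: str | None = None
    harm_background: str | None = None
    behaviour: str | None = None
    p_undiagnosed: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"service {self.code}: unknown kind {self.kind!r}")
        if self.kind in ("net_benefit", "detection", "inline_hr"):
            if self.hr is None or not (0.0 < self.hr <= 1.0):
                raise ValueError(
                    f"service {self.code}: hazard ratio must lie in (0, 1], got {self.hr!r}"
                )
        if self.kind == "detection":
            if self.p_undiagnosed is None or not (0.0 <= self.p_undiagnosed <= 1.0):
                raise ValueError(
                    f"service {self.code}: p_undiagnosed must lie in [0, 1]"
                )

    @property
    def criterion(self) -> dict:
        """The predicate in the dict form ``formulas.eligible_codes`` evaluates."""
        crit = dict(self.criteria)
        crit["code"] = self.code
        return crit


def load_params() -> dict:
    """Load the packaged parameter file (services, adjustments, risk models)."""
    text = resources.files("kocompose.ipp").joinpath("params.yaml").read_text("utf-8")
    params = yaml.safe_load(text)
    codes = list(params["services"])
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate service codes in parameter file")
    return params


def load_catalog(params: dict | None = None) -> list[ServiceDefinition]:
    """Build the service catalog; configuration errors surface here, not at runtime."""
    if params is None:
        params = load_params()
    catalog = []
    for code, spec in params["services"].items():
        catalog.append(
            ServiceDefinition(
                code=code,
                name=spec["name"],
                kind=spec["kind"],
                criteria=spec.get("criteria", {}),
                hr=spec.get("hr"),
                background=spec.get("background"),
                harm_background=spec.get("harm_background"),
                behaviour=spec.get("behaviour"),
                p_undiagnosed=spec.get("p_undiagnosed"),
            )
        )
    return catalog


def eligible_services(features: Mapping[str, Any], catalog: list[ServiceDefinition]) -> list[str]:
    """Codes of exactly the services whose inclusion predicate holds."""
    if not catalog:
        raise ValueError("catalog must be nonempty")
    return formulas.eligible_codes(features, [s.criterion for s in catalog])
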