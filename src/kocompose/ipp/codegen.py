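"""Generate the 42-KO demonstration shelf.

Each submodel becomes an ordinary KO whose payload is generated Python
source. The arithmetic inside payloads is not re-written here: the shared
formula functions are extracted verbatim with ``inspect.getsource`` from
:mod:`kocompose.ipp.formulas` and embedded, so gateway execution and the
in-process reference path (:func:`kocompose.ipp.runner.run_direct`) agree
bit-for-bit. Payloads are therefore self-contained — they import nothing
from this package and reach other models only through the injected
``ko_context`` facility.

Wiring (mixed serial-hierarchical-conditional): the top-level executive has
29 direct callees — 3 lower-level executives (feature derivation, mortality
schedule, diet risk), the criteria submodel, the life-expectancy and
life-gain estimators, the detection-gain estimator, 15 net-benefit
estimators, and 7 background-risk models. The 3 lower-level executives
reference 13 submodel slots (5 derivations; life table + 3 adjustments +
the life-expectancy estimator; 2 diet-risk models + 1 background-risk
model). The life-expectancy estimator is shared between the top level and
the schedule executive, giving 42 distinct submodels overall.
"""

from __future__ import annotations

from inspect import getsource

from kocompose.composition import ModelReference, make_serial_executive
from kocompose.ko_package import (
    DeploymentSpec,
    KnowledgeObjectPackage,
    KoMetadata,
    PersistentId,
    ServiceSpec,
)
from kocompose.ipp import formulas
from kocompose.ipp.catalog import load_catalog
from kocompose.ipp.lifetable import LifeTable

__all__ = ["NAAN", "SUBMODEL_TYPES", "build_shelf_packages"]

NAAN = "99999"
VERSION = "1.0.0"

#: Table-style taxonomy tokens with their expected quantities.
SUBMODEL_TYPES = {
    "executive": 4,
    "feature_derivation": 5,
    "service_criteria": 1,
    "life_table": 1,
    "life_expectancy": 1,
    "life_expectancy_gain": 1,
    "net_benefit": 15,
    "detection_gain": 1,
    "diet_risk": 2,
    "mortality_adjustment": 3,
    "background_risk": 8,
}


def _src(*functions) -> str:
    return "\n\n".join(getsource(fn) for fn in functions)


def _package(
    name: str,
    title: str,
    endpoint_path: str,
    source: str,
    description: str = "",
    function_name: str = "run",
) -> KnowledgeObjectPackage:
    entry = "model.py"
    base_url = f"/ipp/{name}/1.0"
    return KnowledgeObjectPackage(
        metadata=KoMetadata(
            id=PersistentId(NAAN, name, VERSION),
            title=title,
            contributors=("kocompose demo shelf generator",),
            ko_version=VERSION,
            description=description,
        ),
        deployment=DeploymentSpec(
            endpoint_path=endpoint_path,
            engine="python",
            entry=entry,
            artifacts=(entry,),
            function_name=function_name,
        ),
        service=ServiceSpec(
            service_version="1.0",
            title=title,
            base_url=base_url,
            paths=(endpoint_path,),
            description=description,
        ),
        payload={entry: source.encode("utf-8")},
    )


def _key(name: str, endpoint_path: str) -> str:
    return f"/ipp/{name}/1.0{endpoint_path}"


# ---------------------------------------------------------------------------
# Payload templates (constants are substituted with repr)
# ---------------------------------------------------------------------------

_DERIVE_RUN = '''

def run(inputs):
    return {{"features": {call}}}
'''

_CRITERIA_RUN = '''

CRITERIA = {criteria!r}


def run(inputs):
    return {{"eligible": eligible_codes(inputs["features"], CRITERIA)}}
'''

_LIFETABLE_RUN = '''"""Baseline annual mortality probabilities by age, sex, and race (synthetic)."""

TABLE = {table!r}

MAX_AGE = 100


def run(inputs):
    rates = TABLE[inputs["sex"]][inputs["race"]]
    age = int(inputs["age"])
    stop = min(age + int(inputs["horizon"]), MAX_AGE)
    return {{"start_age": age, "rates": list(rates[age : stop + 1])}}
'''

_ADJUST_RUN = '''

SPEC = {spec!r}


def run(inputs):
    features = inputs["features"]
    rr = behaviour_rr(features, SPEC)
    return {{
        "features": features,
        "start_age": inputs["start_age"],
        "rates": scale_hazards(inputs["rates"], rr),
    }}
'''

_LE_RUN = '''

def run(inputs):
    return survival_life_expectancy(inputs["rates"])
'''

_GAIN_RUN = '''

def run(inputs):
    return expectancy_difference(inputs["with"], inputs["without"])
'''

_NET_BENEFIT_RUN = '''

HR = {hr!r}
LE_KEY = {le_key!r}
GAIN_KEY = {gain_key!r}


def run(inputs):
    rates = inputs["rates"]
    treated = scale_hazards(rates, HR)
    le_with = ko_context(LE_KEY, {{"rates": treated}})
    le_without = ko_context(LE_KEY, {{"rates": rates}})
    return ko_context(GAIN_KEY, {{"with": le_with, "without": le_without}})
'''

_DETECTION_RUN = '''

HR = {hr!r}
P_UNDIAGNOSED = {p!r}
LE_KEY = {le_key!r}
GAIN_KEY = {gain_key!r}


def run(inputs):
    rates = inputs["rates"]
    treated = scale_hazards(rates, HR)
    le_with = ko_context(LE_KEY, {{"rates": treated}})
    le_without = ko_context(LE_KEY, {{"rates": rates}})
    gain = ko_context(GAIN_KEY, {{"with": le_with, "without": le_without}})
    return P_UNDIAGNOSED * gain
'''

_DIET_RR_RUN = '''"""Two-level relative risk for maintaining vs not maintaining a healthy diet."""

FEATURE = {feature!r}
ADHERENT_RR = {adherent!r}
NONADHERENT_RR = {nonadherent!r}


def run(inputs):
    features = inputs["features"]
    if FEATURE not in features:
        raise ValueError("required patient feature %r is missing" % (FEATURE,))
    rr = ADHERENT_RR if features[FEATURE] else NONADHERENT_RR
    return {{"rr": rr}}
'''

_DIET_ABS_RUN = '''"""Absolute risk from a baseline probability and a relative risk, capped at 1."""


def run(inputs):
    return {"absolute_risk": min(1.0, inputs["baseline"] * inputs["rr"])}
'''

_BACKGROUND_RUN = '''

INTERCEPT = {intercept!r}
COEFFICIENTS = {coefficients!r}


def run(inputs):
    return logistic(linear_score(inputs["features"], COEFFICIENTS, INTERCEPT))
'''

_SCHEDULE_EXEC_RUN = '''"""Schedule executive: life table lookup, behavioural adjustment, baseline LE."""

LIFETABLE_KEY = {lifetable_key!r}
ADJUSTMENT_KEYS = {adjustment_keys!r}
LE_KEY = {le_key!r}
MAX_AGE = 100


def run(inputs):
    features = inputs["features"]
    age = int(features["age"])
    sched = ko_context(
        LIFETABLE_KEY,
        {{
            "age": age,
            "sex": features["gender"],
            "race": features["race"],
            "horizon": MAX_AGE - age,
        }},
    )
    state = {{"features": features, "start_age": sched["start_age"], "rates": sched["rates"]}}
    for key in ADJUSTMENT_KEYS:
        state = ko_context(key, state)
    baseline_le = ko_context(LE_KEY, {{"rates": state["rates"]}})
    return {{
        "start_age": state["start_age"],
        "rates": state["rates"],
        "baseline_le": baseline_le,
    }}
'''

_DIET_EXEC_RUN = '''"""Diet executive: relative risk, background baseline, absolute risk, effective hazard ratio."""

RR_KEY = {rr_key!r}
BASELINE_KEY = {baseline_key!r}
ABS_KEY = {abs_key!r}
ADHERENT_RR = {adherent!r}


def run(inputs):
    features = inputs["features"]
    rr = ko_context(RR_KEY, {{"features": features}})["rr"]
    baseline = ko_context(BASELINE_KEY, {{"features": features}})
    absolute = ko_context(ABS_KEY, {{"rr": rr, "baseline": baseline}})["absolute_risk"]
    return {{"rr": rr, "absolute_risk": absolute, "hr_effective": ADHERENT_RR / rr}}
'''

_TOP_EXEC_RUN = '''"""Top-level executive for the preventive-services composite.

Derives features, screens eligibility, builds the adjusted mortality
schedule, engages only the relevant estimator submodels (conditional
dispatch), computes five services' benefits inline, and returns the ranked
record of per-service life gains.
"""

ENDPOINTS = {endpoints!r}
SERVICES = {services!r}
ADJUSTMENTS = {adjustments!r}
REQUIRED_FEATURES = {required!r}


def run(inputs):
    patient = inputs.get("patient", inputs)
    features = dict(patient.get("features", patient))
    missing = [key for key in REQUIRED_FEATURES if key not in features]
    if missing:
        raise ValueError("missing required features: " + ", ".join(sorted(missing)))
    features = ko_context(ENDPOINTS["derive"], {{"features": features}})["features"]
    eligible = ko_context(ENDPOINTS["criteria"], {{"features": features}})["eligible"]
    sched = ko_context(ENDPOINTS["schedule"], {{"features": features}})
    rates = sched["rates"]
    baseline_le = sched["baseline_le"]
    background = {{}}
    for bg_name, bg_key in ENDPOINTS["background"].items():
        background[bg_name] = ko_context(bg_key, {{"features": features}})
    gains = {{}}
    for code in eligible:
        meta = SERVICES[code]
        kind = meta["kind"]
        if kind == "net_benefit":
            raw = ko_context(ENDPOINTS["net_benefit"][code], {{"rates": rates}})
            scale = 1.0
            if meta.get("background"):
                scale = scale * background[meta["background"]]
            if meta.get("harm_background"):
                scale = scale * (1.0 - background[meta["harm_background"]])
            gains[code] = raw * scale
        elif kind == "detection":
            gains[code] = ko_context(ENDPOINTS["detection"], {{"rates": rates}})
        elif kind == "diet":
            diet = ko_context(ENDPOINTS["diet_exec"], {{"features": features}})
            adjusted = scale_hazards(rates, diet["hr_effective"])
            le_with = ko_context(ENDPOINTS["life_expectancy"], {{"rates": adjusted}})
            gain = ko_context(
                ENDPOINTS["life_gain"], {{"with": le_with, "without": baseline_le}}
            )
            gains[code] = diet["absolute_risk"] * gain
        elif kind == "inline_behavior":
            rr = behaviour_rr(features, ADJUSTMENTS[meta["behaviour"]])
            if rr <= 1.0:
                gains[code] = 0.0
            else:
                adjusted = scale_hazards(rates, 1.0 / rr)
                le_with = ko_context(ENDPOINTS["life_expectancy"], {{"rates": adjusted}})
                gains[code] = ko_context(
                    ENDPOINTS["life_gain"], {{"with": le_with, "without": baseline_le}}
                )
        else:
            adjusted = scale_hazards(rates, meta["hr"])
            le_with = ko_context(ENDPOINTS["life_expectancy"], {{"rates": adjusted}})
            gain = ko_context(
                ENDPOINTS["life_gain"], {{"with": le_with, "without": baseline_le}}
            )
            scale = 1.0
            if meta.get("background"):
                scale = scale * background[meta["background"]]
            gains[code] = scale * gain
    ranked = sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
    return {{
        "lifeexpectancy": {{
            SERVICES[code]["name"]: {{"total": {{"life-gain": gain}}}}
            for code, gain in gains.items()
        }},
        "ranking": [code for code, _ in ranked],
    }}
'''


# ---------------------------------------------------------------------------
# Shelf assembly
# ---------------------------------------------------------------------------

def build_shelf_packages(
    params: dict, life_table: LifeTable
) -> tuple[list[tuple[KnowledgeObjectPackage, str]], dict]:
    """Build all 42 packages plus the wiring record.

    Returns ``(packages, wiring)`` where packages is a list of
    ``(package, submodel_type)`` and wiring records the top-level endpoint,
    its 29 direct callees, and each lower-level executive's callees.
    """
    catalog = load_catalog(params)  # validates hr ranges at build time
    packages: list[tuple[KnowledgeObjectPackage, str]] = []

    # -- feature derivation (5) + derivation executive -----------------------
    cvd = params["cvd_risk_score"]
    derivations = [
        ("ipp-derive-bmi", "Body mass index derivation",
         _src(formulas.bmi_value, formulas.add_bmi),
         "add_bmi(inputs[\"features\"])"),
        ("ipp-derive-bsa", "Body surface area derivation (Mosteller)",
         _src(formulas.mosteller_bsa, formulas.add_bsa),
         "add_bsa(inputs[\"features\"])"),
        ("ipp-derive-co", "Cardiac output derivation",
         _src(formulas.cardiac_output_value, formulas.add_cardiac_output),
         "add_cardiac_output(inputs[\"features\"])"),
        ("ipp-derive-crcl", "Creatinine clearance derivation (Cockcroft-Gault)",
         _src(formulas.cockcroft_gault, formulas.add_creatinine_clearance),
         "add_creatinine_clearance(inputs[\"features\"])"),
        ("ipp-derive-cvdrisk", "Synthetic logistic cardiovascular risk score",
         _src(formulas.logistic, formulas.linear_score, formulas.add_cvd_risk)
         + f"\n\nINTERCEPT = {cvd['intercept']!r}\nCOEFFICIENTS = {dict(cvd['coefficients'])!r}\n",
         "add_cvd_risk(inputs[\"features\"], INTERCEPT, COEFFICIENTS)"),
    ]
    derive_keys = []
    for name, title, src, call in derivations:
        pkg = _package(name, title, "/derive", src + _DERIVE_RUN.format(call=call))
        packages.append((pkg, "feature_derivation"))
        derive_keys.append(pkg.endpoint_key)

    derive_exec = make_serial_executive(
        [ModelReference(k) for k in derive_keys],
        PersistentId(NAAN, "ipp-derive-exec", VERSION),
        title="Feature derivation executive",
    )
    packages.append((derive_exec, "executive"))

    # -- criteria (1) --------------------------------------------------------
    criteria_pkg = _package(
        "ipp-criteria",
        "Recommended preventive service criteria",
        "/eligible",
        _src(formulas.eligible_codes)
        + _CRITERIA_RUN.format(criteria=[s.criterion for s in catalog]),
        description="inclusion/exclusion criteria for all covered services",
    )
    packages.append((criteria_pkg, "service_criteria"))

    # -- life table (1), adjustments (3), estimators (2) ---------------------
    lifetable_pkg = _package(
        "ipp-lifetable",
        "Baseline mortality life table",
        "/schedule",
        _LIFETABLE_RUN.format(table=life_table.as_nested_dict()),
    )
    packages.append((lifetable_pkg, "life_table"))

    adjustment_keys = []
    for factor, spec in params["adjustments"].items():
        pkg = _package(
            f"ipp-adjust-{factor}",
            f"All-cause mortality adjustment: {factor}",
            "/adjust",
            _src(formulas.step_rr, formulas.behaviour_rr, formulas.scale_hazards)
            + _ADJUST_RUN.format(spec=dict(spec)),
        )
        packages.append((pkg, "mortality_adjustment"))
        adjustment_keys.append(pkg.endpoint_key)

    le_pkg = _package(
        "ipp-life-expectancy",
        "Life expectancy estimator",
        "/le",
        _src(formulas.survival_life_expectancy) + _LE_RUN,
    )
    packages.append((le_pkg, "life_expectancy"))
    le_key = le_pkg.endpoint_key

    gain_pkg = _package(
        "ipp-life-gain",
        "Life expectancy gain estimator",
        "/gain",
        _src(formulas.expectancy_difference) + _GAIN_RUN,
    )
    packages.append((gain_pkg, "life_expectancy_gain"))
    gain_key = gain_pkg.endpoint_key

    # -- background risks (8) ------------------------------------------------
    background_keys: dict[str, str] = {}
    for bg_name, model in params["background_models"].items():
        pkg = _package(
            "ipp-bg-" + bg_name.replace("_", "-"),
            f"Partial background risk: {bg_name}",
            "/risk",
            _src(formulas.logistic, formulas.linear_score)
            + _BACKGROUND_RUN.format(
                intercept=model["intercept"], coefficients=dict(model["coefficients"])
            ),
        )
        packages.append((pkg, "background_risk"))
        background_keys[bg_name] = pkg.endpoint_key

    # -- diet risk (2) + diet executive --------------------------------------
    diet = params["diet"]
    diet_rr_pkg = _package(
        "ipp-diet-rr",
        "Diet relative risk",
        "/rr",
        _DIET_RR_RUN.format(
            feature=diet["feature"],
            adherent=diet["adherent_rr"],
            nonadherent=diet["nonadherent_rr"],
        ),
    )
    diet_abs_pkg = _package(
        "ipp-diet-abs", "Diet absolute risk", "/abs", _DIET_ABS_RUN
    )
    packages.append((diet_rr_pkg, "diet_risk"))
    packages.append((diet_abs_pkg, "diet_risk"))

    diet_exec = _package(
        "ipp-diet-exec",
        "Diet risk executive",
        "/run",
        _DIET_EXEC_RUN.format(
            rr_key=diet_rr_pkg.endpoint_key,
            baseline_key=background_keys["diet_disease"],
            abs_key=diet_abs_pkg.endpoint_key,
            adherent=diet["adherent_rr"],
        ),
    )
    packages.append((diet_exec, "executive"))

    # -- schedule executive ---------------------------------------------------
    schedule_exec = _package(
        "ipp-schedule-exec",
        "Mortality schedule executive",
        "/run",
        _SCHEDULE_EXEC_RUN.format(
            lifetable_key=lifetable_pkg.endpoint_key,
            adjustment_keys=adjustment_keys,
            le_key=le_key,
        ),
    )
    packages.append((schedule_exec, "executive"))

    # -- net benefit (15) and detection (1) -----------------------------------
    nb_keys: dict[str, str] = {}
    detection_key = None
    for service in catalog:
        if service.kind == "net_benefit":
            pkg = _package(
                f"ipp-nb-{service.code.lower()}",
                f"Net benefit estimator: {service.name}",
                "/estimate",
                _src(formulas.scale_hazards)
                + _NET_BENEFIT_RUN.format(hr=service.hr, le_key=le_key, gain_key=gain_key),
            )
            packages.append((pkg, "net_benefit"))
            nb_keys[service.code] = pkg.endpoint_key
        elif service.kind == "detection":
            pkg = _package(
                f"ipp-detect-{service.code.lower()}",
                f"Detection gain estimator: {service.name}",
                "/estimate",
                _src(formulas.scale_hazards)
                + _DETECTION_RUN.format(
                    hr=service.hr,
                    p=service.p_undiagnosed,
                    le_key=le_key,
                    gain_key=gain_key,
                ),
            )
            packages.append((pkg, "detection_gain"))
            detection_key = pkg.endpoint_key

    # -- top-level executive ---------------------------------------------------
    top_backgrounds = {
        name: key for name, key in background_keys.items() if name != "diet_disease"
    }
    endpoints = {
        "derive": derive_exec.endpoint_key,
        "criteria": criteria_pkg.endpoint_key,
        "schedule": schedule_exec.endpoint_key,
        "diet_exec": diet_exec.endpoint_key,
        "life_expectancy": le_key,
        "life_gain": gain_key,
        "detection": detection_key,
        "net_benefit": nb_keys,
        "background": top_backgrounds,
    }
    service_meta = {}
    for service in catalog:
        meta: dict = {"kind": service.kind, "name": service.name}
        if service.background:
            meta["background"] = service.background
        if service.harm_background:
            meta["harm_background"] = service.harm_background
        if service.behaviour:
            meta["behaviour"] = service.behaviour
        if service.kind == "inline_hr":
            meta["hr"] = service.hr
        service_meta[service.code] = meta
    top_pkg = _package(
        "ipp-executive",
        "Preventive services composite executive",
        "/run",
        _src(formulas.step_rr, formulas.behaviour_rr, formulas.scale_hazards)
        + _TOP_EXEC_RUN.format(
            endpoints=endpoints,
            services=service_meta,
            adjustments={k: dict(v) for k, v in params["adjustments"].items()},
            required=tuple(REQUIRED_FEATURES),
        ),
        description="accepts the patient record and returns ranked life gains",
    )
    packages.append((top_pkg, "executive"))

    top_direct = (
        [
            derive_exec.endpoint_key,
            schedule_exec.endpoint_key,
            diet_exec.endpoint_key,
            criteria_pkg.endpoint_key,
            le_key,
            gain_key,
            detection_key,
        ]
        + list(nb_keys.values())
        + list(top_backgrounds.values())
    )
    wiring = {
        "top": top_pkg.endpoint_key,
        "top_direct_callees": top_direct,
        "lower_executives": {
            derive_exec.endpoint_key: derive_keys,
            schedule_exec.endpoint_key: [lifetable_pkg.endpoint_key]
            + adjustment_keys
            + [le_key],
            diet_exec.endpoint_key: [
                diet_rr_pkg.endpoint_key,
                background_keys["diet_disease"],
                diet_abs_pkg.endpoint_key,
            ],
        },
    }
    return packages, wiring


#: The printed patient-record keys every request must carry.
REQUIRED_FEATURES = (
    "age",
    "race",
    "gender",
    "height",
    "weight",
    "systolic",
    "diastolic",
    "totalcholesterol",
    "HDL",
    "LDL",
    "triglycerides",
    "a1c",
    "cvd",
)
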