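"""Self-contained scalar formulas shared by the library and generated payloads.

Every function here is written to be extracted with ``inspect.getsource`` and
embedded verbatim into generated KO payload source, so the library path and
the gateway path execute bit-identical arithmetic. Consequences: no module
imports at top level (``math`` is imported inside the one function that needs
it), no closures, no references to other modules — only to other functions in
this file, which the code generator includes alongside.
"""

__all__ = [
    "bmi_value",
    "mosteller_bsa",
    "cardiac_output_value",
    "cockcroft_gault",
    "logistic",
    "linear_score",
    "step_rr",
    "scale_hazards",
    "survival_life_expectancy",
    "expectancy_difference",
    "add_bmi",
    "add_bsa",
    "add_cardiac_output",
    "add_creatinine_clearance",
    "add_cvd_risk",
    "behaviour_rr",
    "eligible_codes",
]


def bmi_value(height_in, weight_lb):
    """Body mass index from height in inches and weight in pounds."""
    if height_in <= 0:
        raise ValueError("height must be positive")
    return weight_lb / height_in / height_in * 703


def mosteller_bsa(height_cm, weight_kg):
    """Body surface area (m^2), Mosteller formula."""
    return (height_cm * weight_kg / 3600.0) ** 0.5


def cardiac_output_value(stroke_volume_ml, heart_rate_bpm):
    """Cardiac output (mL/min) as stroke volume times heart rate."""
    return stroke_volume_ml * heart_rate_bpm


def cockcroft_gault(age_y, weight_kg, creatinine_mg_dl, female):
    """Creatinine clearance (mL/min), Cockcroft-Gault."""
    clearance = (140.0 - age_y) * weight_kg / (72.0 * creatinine_mg_dl)
    return clearance * 0.85 if female else clearance


def logistic(x):
    import math

    return 1.0 / (1.0 + math.exp(-x))


def linear_score(features, coefficients, intercept):
    """Intercept plus sum of coefficient * feature value; absent features count 0."""
    score = intercept
    for key, beta in coefficients.items():
        value = features.get(key)
        if value is True:
            value = 1.0
        elif value is False or value is None:
            value = 0.0
        score += beta * float(value)
    return score


def step_rr(value, cuts, levels):
    """Step-function relative risk: levels[i] on [cuts[i-1], cuts[i])."""
    for cut, level in zip(cuts, levels):
        if value < cut:
            return level
    return levels[len(cuts)]


def scale_hazards(rates, ratio):
    """Multiply annual mortality probabilities by a ratio, capping each at 1."""
    return [min(1.0, q * ratio) for q in rates]


def survival_life_expectancy(rates):
    """Expected whole years lived over an age-ordered mortality schedule.

    LE = sum over k of the probability of surviving the first k years,
    i.e. sum_k prod_{j<k} (1 - q_j). No half-year correction.
    """
    expectancy = 0.0
    survival = 1.0
    for q in rates:
        if q < 0.0 or q > 1.0:
            raise ValueError("mortality probability outside [0, 1]: %r" % (q,))
        survival *= 1.0 - q
        expectancy += survival
    return expectancy


def expectancy_difference(le_with, le_without):
    """Life gain in years: expectancy with an intervention minus without."""
    return le_with - le_without


def add_bmi(features):
    out = dict(features)
    if out.get("height") and out.get("weight") and out["height"] > 0:
        out["bmi"] = bmi_value(float(out["height"]), float(out["weight"]))
    return out


def add_bsa(features):
    out = dict(features)
    if out.get("height") and out.get("weight"):
        out["bsa"] = mosteller_bsa(float(out["height"]) * 2.54, float(out["weight"]) * 0.45359237)
    return out


def add_cardiac_output(features):
    out = dict(features)
    if out.get("stroke_volume") and out.get("heart_rate"):
        out["cardiac_output"] = cardiac_output_value(
            float(out["stroke_volume"]), float(out["heart_rate"])
        )
    return out


def add_creatinine_clearance(features):
    out = dict(features)
    if out.get("age") and out.get("weight") and out.get("creatinine"):
        out["creatinine_clearance"] = cockcroft_gault(
            float(out["age"]),
            float(out["weight"]) * 0.45359237,
            float(out["creatinine"]),
            out.get("gender") == "Female",
        )
    return out


def add_cvd_risk(features, intercept, coefficients):
    out = dict(features)
    out["cvd_risk"] = logistic(linear_score(out, coefficients, intercept))
    return out


def behaviour_rr(features, spec):
    """All-cause relative risk for one behavioural factor (step-function spec).

    spec kinds: "step" applies a step function to a numeric feature;
    "smoking" uses current/former flags plus pack-years.
    """
    if spec["kind"] == "smoking":
        if features.get(spec["current_flag"]):
            return step_rr(float(features.get(spec["feature"], 0.0)), spec["cuts"], spec["levels"])
        if features.get(spec["former_flag"]):
            return spec["former_rr"]
        return 1.0
    value = features.get(spec["feature"])
    if value is None:
        return 1.0
    return step_rr(float(value), spec["cuts"], spec["levels"])


def eligible_codes(features, criteria):
    """Service codes whose inclusion predicate holds for these features.

    Each criterion may constrain an age range, sex, boolean flags, and
    numeric minima/maxima over raw features. A missing constrained feature
    fails the predicate.
    """
    codes = []
    age = features.get("age")
    for criterion in criteria:
        if age is None or age < criterion.get("min_age", 18) or age > criterion.get("max_age", 200):
            continue
        sex = criterion.get("sex")
        if sex is not None and features.get("gender") != sex:
            continue
        satisfied = True
        for key, expected in (criterion.get("flags") or {}).items():
            if bool(features.get(key, False)) != bool(expected):
                satisfied = False
                break
        if satisfied:
            for key, bound in (criterion.get("min") or {}).items():
                value = features.get(key)
                if value is None or float(value) < bound:
                    satisfied = False
                    break
        if satisfied:
            for key, bound in (criterion.get("max") or {}).items():
                value = features.get(key)
                if value is None or float(value) > bound:
                    satisfied = False
                    break
        if satisfied:
            codes.append(criterion["code"])
    return codes
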