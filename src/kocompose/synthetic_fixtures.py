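"""Synthetic inputs: life tables, patients, toy packages, and the demo shelf.

Everything the stack needs is generated here with no downloads:

* a Gompertz-law life table standing in for a CDC-style table stratified by
  sex and race (plausible magnitudes, not fidelity to any published table);
* 101-feature patient records following the printed input schema (13 printed
  keys plus 88 documented synthetic ones);
* seeded random-but-valid KO packages for round-trip testing;
* the full 42-submodel demonstration shelf, written in standard KO layout
  with a JSON manifest.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
import math
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from kocompose.ko_package import (
    DeploymentSpec,
    KnowledgeObjectPackage,
    KoMetadata,
    PersistentId,
    ServiceSpec,
    validate_package,
    write_package,
)
from kocompose.ipp.catalog import load_params
from kocompose.ipp.codegen import REQUIRED_FEATURES, build_shelf_packages
from kocompose.ipp.lifetable import MAX_AGE, LifeTable, write_life_table

__all__ = [
    "GompertzParams",
    "ShelfManifest",
    "FEATURE_SPECS",
    "ARCHETYPES",
    "gen_life_table",
    "gen_patient",
    "gen_random_package",
    "make_bmi_fixture",
    "build_demo_shelf",
]


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GompertzParams:
    """Gompertz mortality law q(a) = min(1, m_sex * m_race * A * exp(B * a)).

    Defaults give a 50-year-old a remaining life expectancy in a plausible
    25-35 year band; chosen for plausibility, not fidelity.
    """

    baseline: float = 5e-5  # A: hazard at age 0
    slope: float = 0.085  # B: log-hazard increase per year
    sex_multipliers: tuple[tuple[str, float], ...] = (("Female", 0.82), ("Male", 1.0))
    race_multipliers: tuple[tuple[str, float], ...] = (
        ("Black", 1.12),
        ("Other", 0.95),
        ("White", 1.0),
    )

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.slope <= 0:
            raise ValueError("Gompertz baseline and slope must be positive")


def gen_life_table(seed: int = 0, params: GompertzParams = GompertzParams()) -> LifeTable:
    """Build the synthetic life table (deterministic function of its parameters).

    The seed is accepted for interface symmetry with the other generators;
    the table itself carries no random noise, which keeps the required
    monotone-in-age property exact.
    """
    del seed  # determinism is trivial: the table is a pure function of params
    strata: dict[tuple[str, str], tuple[float, ...]] = {}
    for sex, m_sex in params.sex_multipliers:
        for race, m_race in params.race_multipliers:
            rates = [
                min(1.0, m_sex * m_race * params.baseline * math.exp(params.slope * age))
                for age in range(MAX_AGE + 1)
            ]
            if any(q >= 1.0 for q in rates[:60]):
                warnings.warn(
                    f"stratum ({sex}, {race}) saturates q=1 before age 60; "
                    "implausible Gompertz parameters",
                    stacklevel=2,
                )
            rates[MAX_AGE] = 1.0  # closure
            strata[(sex, race)] = tuple(rates)
    return LifeTable(strata)


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------

# Generation spec per feature: ("int", lo, hi) | ("float", lo, hi) |
# ("bool", p_true) | ("choice", options). The first 13 are the printed input
# keys; the remaining 88 are synthetic stand-ins for the unprinted ones,
# named for what they would plausibly record.
FEATURE_SPECS: dict[str, tuple] = {
    # printed keys
    "age": ("int", 18, 90),
    "race": ("choice", ("Black", "Other", "White")),
    "gender": ("choice", ("Female", "Male")),
    "height": ("float", 58.0, 76.0),
    "weight": ("float", 100.0, 280.0),
    "systolic": ("int", 95, 180),
    "diastolic": ("int", 55, 110),
    "totalcholesterol": ("int", 120, 280),
    "HDL": ("int", 25, 90),
    "LDL": ("int", 50, 200),
    "triglycerides": ("int", 50, 400),
    "a1c": ("float", 4.5, 12.0),
    "cvd": ("bool", 0.15),
    # tobacco and related exposures
    "current_smoker": ("bool", 0.2),
    "ever_smoker": ("bool", 0.45),
    "pack_years": ("float", 0.0, 60.0),
    "years_since_quit": ("float", 0.0, 30.0),
    "smokeless_tobacco": ("bool", 0.05),
    "vaping": ("bool", 0.08),
    # alcohol and substances
    "drinks_per_week": ("float", 0.0, 30.0),
    "binge_episodes_month": ("int", 0, 8),
    "substance_use_disorder": ("bool", 0.04),
    "caffeine_cups_day": ("int", 0, 6),
    # diet and activity
    "diet_adherent": ("bool", 0.4),
    "fruit_servings_day": ("float", 0.0, 5.0),
    "vegetable_servings_day": ("float", 0.0, 5.0),
    "red_meat_servings_week": ("float", 0.0, 10.0),
    "sodium_mg_day": ("int", 1500, 5000),
    "exercise_minutes_week": ("int", 0, 400),
    "sedentary_hours_day": ("float", 2.0, 14.0),
    "sleep_hours": ("float", 4.0, 10.0),
    # vitals and anthropometrics
    "heart_rate": ("int", 50, 105),
    "stroke_volume": ("float", 55.0, 100.0),
    "respiratory_rate": ("int", 10, 22),
    "temperature_f": ("float", 97.0, 99.5),
    "waist_inches": ("float", 24.0, 55.0),
    "resting_spo2": ("int", 92, 100),
    # laboratory values
    "creatinine": ("float", 0.5, 2.5),
    "egfr": ("float", 30.0, 120.0),
    "fasting_glucose": ("int", 70, 220),
    "alt": ("int", 10, 80),
    "ast": ("int", 10, 80),
    "tsh": ("float", 0.4, 6.0),
    "vitamin_d": ("float", 10.0, 60.0),
    "hemoglobin": ("float", 10.0, 18.0),
    "wbc": ("float", 3.5, 12.0),
    "platelets": ("int", 120, 450),
    "crp": ("float", 0.1, 12.0),
    "urate": ("float", 2.5, 9.0),
    # diagnosis history
    "hypertension_dx": ("bool", 0.3),
    "diabetes_dx": ("bool", 0.12),
    "ckd": ("bool", 0.06),
    "copd": ("bool", 0.06),
    "asthma": ("bool", 0.09),
    "afib": ("bool", 0.04),
    "stroke_history": ("bool", 0.03),
    "mi_history": ("bool", 0.04),
    "cancer_history": ("bool", 0.06),
    "depression_dx": ("bool", 0.12),
    "anxiety_dx": ("bool", 0.12),
    "osteoporosis_dx": ("bool", 0.05),
    "liver_disease": ("bool", 0.03),
    "hiv_positive": ("bool", 0.005),
    # family history
    "family_history_cvd": ("bool", 0.25),
    "family_history_crc": ("bool", 0.08),
    "family_history_breast": ("bool", 0.08),
    "family_history_diabetes": ("bool", 0.2),
    "family_history_aaa": ("bool", 0.03),
    "family_history_osteoporosis": ("bool", 0.08),
    # medications
    "on_statin": ("bool", 0.2),
    "on_aspirin": ("bool", 0.15),
    "on_antihypertensive": ("bool", 0.25),
    "on_metformin": ("bool", 0.1),
    "on_insulin": ("bool", 0.04),
    "on_anticoagulant": ("bool", 0.04),
    "on_ssri": ("bool", 0.1),
    "on_bisphosphonate": ("bool", 0.03),
    # screening and immunization history
    "last_colonoscopy_years": ("float", 0.0, 20.0),
    "last_mammogram_years": ("float", 0.0, 10.0),
    "last_pap_years": ("float", 0.0, 10.0),
    "last_hiv_test_years": ("float", 0.0, 20.0),
    "last_lipid_panel_years": ("float", 0.0, 10.0),
    "last_a1c_test_years": ("float", 0.0, 5.0),
    "flu_vaccine_this_year": ("bool", 0.45),
    "tdap_last10y": ("bool", 0.55),
    "zoster_vaccinated": ("bool", 0.25),
    "pneumococcal_vaccinated": ("bool", 0.3),
    "last_dexa_years": ("float", 0.0, 10.0),
    "last_eye_exam_years": ("float", 0.0, 6.0),
    # psychosocial and functional
    "sexually_active": ("bool", 0.6),
    "pregnant": ("bool", 0.02),
    "menopause": ("bool", 0.3),
    "falls_last_year": ("int", 0, 4),
    "adl_limitations": ("int", 0, 5),
    "phq2_score": ("int", 0, 6),
    "audit_c_score": ("int", 0, 12),
    "gad2_score": ("int", 0, 6),
    "health_literacy": ("choice", ("high", "low", "medium")),
    "insurance": ("choice", ("medicaid", "medicare", "none", "private")),
    "rural_residence": ("bool", 0.2),
    "lives_alone": ("bool", 0.25),
}

# Overrides that make one patient satisfy every service's inclusion
# criterion simultaneously (the age ranges intersect only at 65).
_ELIGIBLE_ALL = {
    "age": 65,
    "gender": "Female",
    "race": "White",
    "height": 62.0,
    "weight": 180.0,
    "systolic": 145,
    "diastolic": 88,
    "totalcholesterol": 230,
    "HDL": 40,
    "LDL": 150,
    "triglycerides": 180,
    "a1c": 7.2,
    "cvd": False,
    "current_smoker": True,
    "ever_smoker": True,
    "pack_years": 25.0,
    "drinks_per_week": 10.0,
    "sexually_active": True,
    "diet_adherent": False,
}

#: Qualitative case archetypes (override sets); their rankings are not
#: reproduction targets — the real coefficients are unpublished.
ARCHETYPES: dict[str, dict] = {
    "heavy_smoker": {"current_smoker": True, "ever_smoker": True, "pack_years": 45.0, "age": 60},
    "heavy_drinker": {"drinks_per_week": 25.0, "binge_episodes_month": 6, "age": 50},
    "uncontrolled_hypertensive": {"systolic": 170, "diastolic": 105, "hypertension_dx": True},
    "uncontrolled_diabetic": {"a1c": 10.5, "diabetes_dx": True, "fasting_glucose": 210},
    "obese_sedentary": {"weight": 270.0, "height": 64.0, "exercise_minutes_week": 0},
    "poor_diet": {"diet_adherent": False, "fruit_servings_day": 0.0, "red_meat_servings_week": 9.0},
    "older_female_never_screened": {
        "age": 68,
        "gender": "Female",
        "last_mammogram_years": 10.0,
        "last_colonoscopy_years": 20.0,
    },
    "older_male_smoker": {"age": 70, "gender": "Male", "ever_smoker": True, "pack_years": 35.0},
    "high_cholesterol": {"totalcholesterol": 280, "LDL": 195, "HDL": 28},
    "young_low_risk": {"age": 25, "current_smoker": False, "ever_smoker": False, "cvd": False},
    "cvd_survivor": {"cvd": True, "mi_history": True, "on_statin": True, "age": 66},
    "frail_elder": {"age": 82, "falls_last_year": 3, "adl_limitations": 4},
}


def _draw(rng: random.Random, spec: tuple):
    kind = spec[0]
    if kind == "int":
        return rng.randint(spec[1], spec[2])
    if kind == "float":
        return round(rng.uniform(spec[1], spec[2]), 2)
    if kind == "bool":
        return rng.random() < spec[1]
    if kind == "choice":
        return rng.choice(spec[1])
    raise ValueError(f"unknown feature spec kind {kind!r}")


def gen_patient(seed: int, profile: str = "random") -> dict:
    """Generate a complete patient feature record (>= 101 keys).

    Profiles: ``random``, ``eligible_all`` (satisfies every service's
    inclusion criterion), or a named archetype from :data:`ARCHETYPES`.
    """
    rng = random.Random(seed)
    features = {name: _draw(rng, spec) for name, spec in FEATURE_SPECS.items()}
    # keep smoking fields internally consistent
    if features["current_smoker"]:
        features["ever_smoker"] = True
    if not features["ever_smoker"]:
        features["pack_years"] = 0.0
        features["years_since_quit"] = 0.0
    if profile == "random":
        pass
    elif profile == "eligible_all":
        features.update(_ELIGIBLE_ALL)
    elif profile in ARCHETYPES:
        features.update(ARCHETYPES[profile])
    else:
        raise ValueError(
            f"unknown profile {profile!r}: expected 'random', 'eligible_all', "
            f"or one of {sorted(ARCHETYPES)}"
        )
    return features


# ---------------------------------------------------------------------------
# Toy packages
# ---------------------------------------------------------------------------

_BMI_SOURCE = '''\
def bmi(inputs):
    height = inputs["features"]["height"]  # height in inches
    weight = inputs["features"]["weight"]  # weight in pounds
    return weight / height / height * 703
'''


def make_bmi_fixture() -> KnowledgeObjectPackage:
    """The classic body-mass-index calculator KO used throughout the tests."""
    entry = "bmi.py"
    return KnowledgeObjectPackage(
        metadata=KoMetadata(
            id=PersistentId("99999", "bmicalculator", "1.0.0"),
            title="BMI Calc",
            contributors=("kocompose fixtures",),
            ko_version="1.0.0",
            description="Calculates BMI",
        ),
        deployment=DeploymentSpec(
            endpoint_path="/bmi",
            engine="python",
            entry=entry,
            artifacts=(entry,),
            function_name="bmi",
        ),
        service=ServiceSpec(
            service_version="1.0",
            title="BMI Calc",
            base_url="/ipp/bmicalculator/1.0",
            paths=("/bmi",),
            license_name="GNU General Public License v3 (GPL-3)",
            contact="KGrid-style demo",
            description="Calculates BMI",
        ),
        payload={entry: _BMI_SOURCE.encode("utf-8")},
    )


_WORDS = (
    "alpha", "bravo", "cedar", "delta", "ember", "fjord", "gamma", "harbor",
    "indigo", "juniper", "kelp", "lumen", "maple", "nimbus", "onyx", "pike",
)


def gen_random_package(seed: int) -> KnowledgeObjectPackage:
    """A seeded random — but always valid — KO package for round-trip tests."""
    rng = random.Random(seed)
    naan = str(rng.randint(10000, 99999))
    name = f"{rng.choice(_WORDS)}-{rng.choice(_WORDS)}-{rng.randint(0, 999)}"
    major, minor, patch = rng.randint(0, 9), rng.randint(0, 9), rng.randint(0, 9)
    version = f"{major}.{minor}.{patch}"
    service_version = f"{major}.{minor}"
    path = "/" + rng.choice(_WORDS)
    entry = "model.py"
    constant = rng.randint(-1000, 1000)
    payload = {
        entry: f"def run(inputs):\n    return {constant} + inputs.get('x', 0)\n".encode()
    }
    artifacts = [entry]
    if rng.random() < 0.5:
        helper = f"{rng.choice(_WORDS)}.py"
        if helper != entry:
            payload[helper] = f"# helper constants\nOFFSET = {rng.randint(0, 99)}\n".encode()
            artifacts.append(helper)
    extra_paths = (path,) if rng.random() < 0.7 else (path, path + "-alt")
    return KnowledgeObjectPackage(
        metadata=KoMetadata(
            id=PersistentId(naan, name, version),
            title=f"Random model {name}",
            contributors=tuple(
                f"contributor-{rng.randint(0, 99)}" for _ in range(rng.randint(0, 3))
            ),
            ko_version=version,
            description=f"seeded random package {seed}",
        ),
        deployment=DeploymentSpec(
            endpoint_path=path,
            engine="python",
            entry=entry,
            artifacts=tuple(artifacts),
            function_name="run",
        ),
        service=ServiceSpec(
            service_version=service_version,
            title=f"Random model {name}",
            base_url=f"/{naan}/{name}/{service_version}",
            paths=extra_paths,
            license_name="MIT" if rng.random() < 0.5 else "",
            contact="fixtures",
        ),
        payload=payload,
    )


# ---------------------------------------------------------------------------
# Demo shelf
# ---------------------------------------------------------------------------

@dataclass
class ShelfManifest:
    """What was written where: packages, type counts, and executive wiring."""

    seed: int
    packages: list[dict] = field(default_factory=list)
    counts_by_type: dict[str, int] = field(default_factory=dict)
    wiring: dict = field(default_factory=dict)
    shelf_dir: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "packages": self.packages,
                "counts_by_type": self.counts_by_type,
                "wiring": self.wiring,
            },
            indent=2,
        )

    @classmethod
    def load(cls, shelf_dir: str | Path) -> "ShelfManifest":
        doc = json.loads((Path(shelf_dir) / "manifest.json").read_text("utf-8"))
        return cls(
            seed=doc["seed"],
            packages=doc["packages"],
            counts_by_type=doc["counts_by_type"],
            wiring=doc["wiring"],
            shelf_dir=str(shelf_dir),
        )


def build_demo_shelf(
    shelf_dir: str | Path,
    seed: int = 0,
    gompertz: GompertzParams = GompertzParams(),
) -> ShelfManifest:
    """Write the full 42-KO demonstration shelf under ``shelf_dir``.

    Emits one validated KO package directory per submodel, the synthetic life
    table as CSV (for inspection and reuse), and ``manifest.json`` recording
    the packages, type counts, and wiring. Byte-reproducible per seed.
    """
    shelf_dir = Path(shelf_dir)
    shelf_dir.mkdir(parents=True, exist_ok=True)
    params = load_params()
    table = gen_life_table(seed, gompertz)
    packages, wiring = build_shelf_packages(params, table)

    manifest = ShelfManifest(seed=seed, wiring=wiring, shelf_dir=str(shelf_dir))
    for pkg, type_token in packages:
        report = validate_package(pkg)
        if not report.ok:
            raise RuntimeError(
                f"generated package {pkg.metadata.id} is invalid: {report.to_json()}"
            )
        write_package(pkg, shelf_dir / pkg.metadata.id.name)
        manifest.packages.append(
            {
                "puid": str(pkg.metadata.id),
                "type": type_token,
                "engine": pkg.deployment.engine,
                "endpoint": pkg.endpoint_key,
            }
        )
        manifest.counts_by_type[type_token] = manifest.counts_by_type.get(type_token, 0) + 1

    write_life_table(table, shelf_dir / "lifetable.csv")
    (shelf_dir / "manifest.json").write_text(manifest.to_json(), "utf-8")
    return manifest
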