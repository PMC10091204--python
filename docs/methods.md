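# Methods

## Knowledge Object format

A package is a directory or zip with `metadata.json`, `deployment.yaml`,
`service.yaml`, and payload source files at the root. The layout and the
plain-JSON metadata vocabulary (PUID, title, contributors, KO version,
description) are this package's own conventions; richer linked-data metadata
is out of scope. The PUID is rendered ark-like as `naan/name/version`, with
versions constrained to `MAJOR.MINOR[.PATCH]`.

Deployment descriptions use the one-endpoint dialect: a single top-level
path key, a single `post` method block, and `engine`/`entry`/`artifact`/
`function` fields. A scalar `artifact` normalizes to a one-element list;
a missing `artifact` defaults to the entry file. Multi-endpoint or non-POST
documents are rejected with explicit errors — every worked example of the
format has exactly one POST endpoint, and permitting more would complicate
the runtime-context key model for no demonstrated benefit.

Service descriptions are the consumed slice of OpenAPI 3.0: `info.version`
(the *service* version, deliberately distinct from the KO version),
`servers[0].url` as the partial base URL, and `paths` in document order.
Validation (never raised, always returned as findings) checks artifact
presence, deployment-path/service-path agreement, PUID and version
well-formedness, that the base URL ends with the service-version segment
(e.g. `/ipp/bmicalculator/1.0`), and warns on engines without a registered
adapter. `ok` is exactly the absence of error-severity findings.

## Activation and the gateway

The activator joins `service.base_url + deployment.endpoint_path` into the
endpoint key — both halves appear in the descriptors but no join rule is
dictated by the format, so the concatenation is fixed here and tested.
Activation is atomic: on any failure (unknown engine, payload that will not
load) the context's active set is untouched and a `failed` entry is recorded
separately, so one bad package never blocks a shelf. Re-activation of an
occupied endpoint is an error unless `replace=True`; reproducible shelves
beat silent mutation.

The shipped adapter executes payload source with `exec` in an isolated
per-deployment namespace, in-process. The model-to-model facility is
injected into that namespace under the name `ko_context` at invocation time
(and removed afterwards), so payload code never imports anything from this
package and stays engine-agnostic; adapters for other runtimes implement
the same four-method contract. Payloads are assumed pure and stateless.
Model exceptions surface as `model_error` gateway responses carrying the
model's endpoint key; the gateway itself never crashes on them.
`max_call_depth` (default 32) breaks circular compositions, which the
composition pattern itself does not forbid. Activation wall time is logged,
never asserted — it is hardware-dependent.

## Composition

Serial and conditional executives are generated as small source payloads
from reference lists; a hierarchical composite is simply a serial executive
whose references include another executive, so no third code path exists.
`input_mapping` (upstream field → downstream field) defaults to identity.
Executives are ordinary KOs: inspectable, writable, shippable. The
reference list is embedded in the generated code rather than declared in
metadata; that keeps the executive payload the single source of truth for
what it calls.

## The preventive-services composite

**Life expectancy.** LE = Σ_{k=1..H} Π_{j<k}(1 − q_j): expected whole years
lived, the discrete survival sum without half-year correction — the simplest
convention consistent with an annual-probability schedule. It is isolated in
one estimator submodel so the convention can be swapped. Schedules run from
the patient's age to 100, where the life table closes with q₁₀₀ = 1.

**Net benefit.** A service's effect is modelled as an all-cause hazard ratio
h ∈ (0, 1] applied multiplicatively to the adjusted schedule with a cap at
1; the benefit is LE(min(1, h·q)) − LE(q). This is the minimal mechanism
giving every estimator the same semantics; h = 1 yields exactly zero gain,
and gains are nonincreasing in h. Where configured, the gain is scaled by a
logistic background probability (and for aspirin additionally by one minus a
bleeding-risk probability), giving the eight partial background-risk
submodels their role.

**Behavioural services.** Obesity, alcohol, and tobacco enter twice: as
step-function relative risks multiplied into the baseline schedule
(sequentially, each capped at 1 — with all RR ≥ 1 this equals the one-shot
product), and as the inline benefit of the matching service, computed by
re-scaling the adjusted schedule by 1/RR. A patient with RR = 1 gains
exactly 0 from that service. The diet service combines a two-level
adherence relative risk with the diet-disease background probability as its
absolute-risk baseline.

**Wiring.** The top-level executive calls 29 submodels directly — the three
lower-level executives (feature derivation; schedule building; diet risk),
the criteria model, the life-expectancy and life-gain estimators, the
detection-gain estimator, the 15 net-benefit estimators, and 7
background-risk models — and computes five services (DIET, ALC, SMO, WEI,
STA) inline. The three lower executives reference 13 submodel slots; the
life-expectancy estimator is referenced both by the top level and by the
schedule executive, which is how 1 + 29 + 13 references resolve to 42
distinct submodels. Only eligible services' estimators are engaged per
request (conditional dispatch inside the top executive); the call log
verifies exclusivity.

**Service catalog.** 21 services. Twelve codes (AAA, ALC, ASA, BP, BRE,
CRC, DIA, DIET, STA, SMO, WEI, LUN) follow common preventive-services
abbreviations; the other nine (HIV, CER, OST, DEP, CHL, HCV, IMM, FAL, PRE)
are this package's own additions to reach the full count. Inclusion
criteria are synthetic but mutually satisfiable: the age ranges intersect
only at 65, and only female-restricted services exist, so one engineered
65-year-old female record satisfies all 21 predicates (the `eligible_all`
profile). Criteria reference raw input features only, keeping the criteria
submodel independent of the derivation executive.

**Bit-exact dual path.** All arithmetic lives in
`kocompose/ipp/formulas.py`, written import-free so the shelf generator can
embed each function's source verbatim (`inspect.getsource`) into payloads.
The in-process reference path (`run_direct`) calls the same functions in the
same order, so gateway and direct results are compared with exact equality,
not tolerances — the equivalence tests exercise the gateway plumbing and
the executive glue, with no numerical slack to hide routing errors.

## Synthetic data

**Life table.** Gompertz law q(a) = min(1, m_sex · m_race · A·e^{B·a}) with
A = 5·10⁻⁵, B = 0.085 per year, sex multipliers (Female 0.82, Male 1.0) and
race multipliers (Black 1.12, Other 0.95, White 1.0); q₁₀₀ forced to 1.
Parameters were chosen once so a 50-year-old's remaining expectancy falls in
a plausible 25–35-year band — plausibility, not fidelity to any published
table. The generator takes a seed for interface symmetry but adds no noise:
seeded noise would break the required monotone-in-age property.

**Patients.** 101 features: the 13 printed input keys (age … cvd) plus 88
documented synthetic ones (exposures, labs, diagnoses, family history,
medications, screening history, psychosocial items), each drawn from a
bounded range or category set under `random.Random(seed)`. Smoking fields
are kept internally consistent. The 12 named archetypes are qualitative
override sets only; their rankings are not reference values, since every
coefficient in the system is synthetic.

**What passing tests do not show.** The composite's numeric outputs have no
clinical validity: hazard ratios, risk coefficients, and the life table are
placeholders. Tests demonstrate the architecture — format round-trips,
activation semantics, gateway transparency, conditional exclusivity,
closed-form agreement of the estimators, and structural conformance of the
42-submodel wiring — not the accuracy of any life-gain estimate. Real use
would swap `params.yaml` and the life table for fitted values.

## Numerical and design notes

- Ranking sorts descending by gain with lexicographic tie-break on code;
  deterministic output beats unstable ties.
- `scale_hazards` caps each q at 1 *after* multiplication; sequential
  adjustment is the canonical order (obesity, alcohol, tobacco as
  configured), and tests pin sequential ≡ joint.
- Degenerate inputs: q outside [0, 1] raises; height ≤ 0 raises in BMI; a
  missing derivation input skips only that derived feature; a missing
  diet-adherence feature is an error naming it; an incomplete patient
  record fails fast listing all missing printed keys.
- Life-table CSV I/O writes each q in shortest round-tripping decimal form
  and reads with round-trip float parsing, so table → CSV → table is exact.
- Zip packages are written with a fixed timestamp so archives are
  byte-reproducible.
- The HTTP layer is stdlib (`http.server`) behind the same `Activator`
  routing used in-process; responses serialize the gateway body with sorted
  keys so served and direct results can be compared byte-for-byte.
- Problem sizes in the test suite (≤ 50 synthetic patients for equivalence
  and exclusivity sweeps, 20 random packages for round-trips, 100-year
  horizons) were chosen as the smallest sizes that exercise every branch of
  the wiring; all suites run in seconds on one CPU.

## Limitations

- No authentication, TLS, or multi-process deployment; the gateway is
  in-process and the HTTP server is a thin demonstration wrapper.
- Only the Python adapter ships; Node/R engines are recognized tokens with
  no runtime behind them (activation records a clean failure).
- Stateful models are unsupported by design; payloads must be pure
  functions.
- Pointer-style packages referencing externally hosted models are
  deliberately rejected: payload content must be explicit code or data.
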