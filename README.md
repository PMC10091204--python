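# kocompose

Package, activate, and compose computable biomedical knowledge (CBK) models
as **Knowledge Objects** — and demonstrate the approach by composing a
42-submodel preventive-services model that ranks an individual's recommended
services by estimated life gain.

## The problem

Biomedical results are increasingly shipped as small executable models: a
risk score, a life-table calculation, an eligibility rule. Learning health
systems need to *combine* such models — built by different teams, in
different languages — into composite models without rewriting them. This
package implements a composition method built on three pieces:

1. **Knowledge Objects (KOs).** A KO is a compound digital object holding an
   executable model together with metadata (including a persistent unique
   identifier `naan/name/version`), a deployment description (runtime engine,
   entry artifact, instantiable function), and an OpenAPI 3.0 service
   description (base URL, endpoint path). KOs are plain directories or zip
   archives, so they can be stored, shared, and versioned like any artifact.
2. **An activator / API gateway.** The `Activator` deploys packaged functions
   into a runtime through an adapter (a Python in-process adapter ships;
   other engines implement the same contract), registers each deployment in
   its **runtime context** (a live registry keyed by endpoint), routes
   external requests, and resolves model-to-model references so any deployed
   model can call any other without knowing its implementation.
3. **Executive submodels.** Composites — serial, hierarchical, conditional,
   and mixtures — are expressed as ordinary KOs whose generated payload
   encodes the procedural logic: which models to call, in what order, under
   what conditions.

## The demonstration composite

The demo wires 42 submodels of 11 types (4 executives, 5 feature
derivations, 1 eligibility-criteria model, 1 life table, 1 life-expectancy
estimator, 1 life-gain estimator, 15 net-benefit estimators, 1
detection-gain estimator, 2 diet-risk models, 3 mortality-risk adjustments,
8 partial background-risk models) into a model that, for a patient record
with ≥101 features, ranks 21 preventive services by estimated life gain in
years.

The core quantity is a discrete survival-sum life expectancy over an
age-ordered mortality schedule *q*<sub>a</sub>:

    LE = Σ_{k=1..H} Π_{j<k} (1 − q_j)

A service with all-cause hazard ratio *h* ∈ (0, 1] changes the schedule to
min(1, *h·q*<sub>a</sub>), and its **net benefit** is the life-gain
difference LE(*h·q*) − LE(*q*), optionally scaled by a logistic background
probability that the targeted disease is relevant. Behavioural services
(smoking, alcohol, weight) instead remove the corresponding step-function
relative risk from the individually adjusted schedule. All coefficients are
synthetic placeholders held in one parameter file
(`src/kocompose/ipp/params.yaml`); the architecture, not the clinical
numbers, is the point. Inputs are emulated by `kocompose.synthetic_fixtures`
(Gompertz life table, 101-feature patients, the full shelf).

## Worked example

```sh
kocompose build-demo shelf --seed 7     # writes 42 validated KO packages
kocompose run-ipp --shelf shelf --seed 7
```

The second command activates the shelf, generates a synthetic patient that
satisfies every service's inclusion criteria (a 65-year-old female smoker
with hypertension, diabetes, and elevated LDL), posts the record to the
top-level executive, and prints the ranked output. Highlights of the actual
output:

```text
ranking: SMO, DIA, WEI, BP, ALC, ...
smokingCessation  total life-gain  5.19873809883264
diabetesControl   total life-gain  1.2620169151220644
aspirinPrevention total life-gain  0.14695483822797345
crcScreening      total life-gain  0.051409484765082905
```

Read: under the synthetic parameters, quitting smoking would add about 5.2
expected years for this patient, controlling diabetes about 1.3 years, and
colorectal-cancer screening about 0.05 years (a small hazard reduction
scaled by a modest background colorectal-cancer probability). Each service
appears in the output as `{"<service>": {"total": {"life-gain": years}}}`.

Single models work the same way; the classic body-mass-index KO returns
29.0223 for a 73-inch, 220-pound patient:

```sh
kocompose call /ipp/bmicalculator/1.0/bmi --shelf <dir> --json patient.json
```

`kocompose serve --shelf <dir> --port 8080` exposes the same endpoints over
HTTP (`POST <endpoint>`, `GET /context`).

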