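# Methods

## The staging model

Cardiovascular-kidney-metabolic (CKM) syndrome is staged 0–4 along a
continuum from no risk factors (0), through excess or dysfunctional
adiposity (1) and established metabolic disease or moderate/high-risk CKD
(2), to subclinical cardiovascular disease or very high-risk CKD (3) and
overt clinical cardiovascular disease (4, split into 4A without and 4B
with kidney failure). `ckmstage` operationalizes these stages over
ICD-10-CM diagnosis claims, optionally augmented with structured
measurements, as three composable layers:

1. **Code-set registry** (`ckmstage.registry`). Each stage row is a set of
   named code sets whose patterns are literals, family prefixes (the
   machine form of `I25.-` shorthand), or explicit ranges
   (`Z68.25-Z68.45`), with subtractive exclusions. Codes are stored
   dotless and uppercase; descendant inclusion is always explicit, never
   inferred from shorthand. Range matching uses lexicographic comparison
   with the candidate truncated to the upper bound's length, so `I60-I64`
   captures `I63.9` and `N18.30-N18.32` does not capture `N18.4`. The
   registry ships as canonical JSON (`data/registry_fy2026.json`, pinned
   to FY2026 ICD-10-CM conventions) with a flattened CSV export for
   review; `export(load(x))` is byte-identical on the shipped file.

2. **Encounter confirmation** (`ckmstage.ascertainment`). Within the
   lookback window a *chronic* condition is confirmed by ≥1 inpatient
   claim, or ≥2 outpatient claims on distinct dates with at least one
   pair ≥30 days apart (equivalently: the span of matching outpatient
   dates reaches the threshold). An *acute* event (myocardial
   infarction, stroke) is confirmed by a single inpatient claim. All
   thresholds are inclusive (exactly 30 days confirms) and tunable via
   `ConfirmationPolicy` for sensitivity analyses.

3. **Hierarchical assignment** (`ckmstage.staging`). All code sets are
   ascertained once per patient; stage eligibilities 1–4 are evaluated;
   the patient receives the highest eligible stage, 0 when none fires.
   Stage 2 fires on confirmed hypertension (I10, I11.9, I13.10; I12.-
   with an N18.- code in the window), hypertriglyceridemia (E78.1; E78.2
   only when the expanded proxy is enabled), metabolic syndrome
   (E88.810), diabetes (E11.- including E11.A, E10.-, E13.-), or the
   moderate/high-risk CKD proxy (N18.30–N18.32 confirmed, or N18.1–N18.2
   confirmed with an R80.- code present). Stage 4 requires a confirmed
   clinical-CVD set *and* co-occurring CKM context (a confirmed stage
   1–3 core condition or any N18.- code in the window); 4B requires
   confirmed ESRD (N18.6) and/or a dialysis-dependence code (Z99.2)
   present, with kidney-transplant status (Z94.0 + N18.-) available
   behind a config flag.

## Lookback window

The window is the half-open calendar interval
`[index_date − lookback_months, index_date)`, with months subtracted as
calendar months (day-of-month preserved, clamped at month end). The
index date itself is excluded so that index-day events cannot contaminate
baseline staging; `include_index_date` closes the interval for
sensitivity analyses. Default lookback is 24 months.

## Claims-only vs EHR-enhanced mode

Subclinical disease is poorly visible in claims, so claims-only stage 3
is a conservative proxy: confirmed very high-risk CKD (N18.4–N18.5). In
`ehr_enhanced` mode stage 3 additionally fires when structured
measurements show subclinical atherosclerosis (positive coronary-artery
calcification, or atherosclerosis on CT angiography/catheterization),
subclinical heart failure (NT-proBNP ≥125 pg/mL; hs-TnT ≥14 ng/L women /
≥22 ng/L men; hs-TnI ≥10 / ≥12 ng/L; or an abnormal-echo flag), a KDIGO
very-high-risk or G4–G5 category computed from eGFR and uACR, or an
externally supplied high-10-year-risk flag — always in CKM context
(confirmed stage 1/2 core condition or any CKD code). The two modes can
differ only through stage-3 eligibility. The KDIGO eGFR×albuminuria heat
map ships as an editable, version-labelled data table
(`data/kdigo_grid.json`) rather than being hard-coded. Predicted
10-year cardiovascular risk is accepted only as a boolean input; no risk
equation is computed.

Measurement units are fixed (uACR mg/g, eGFR mL/min/1.73 m², glucose and
lipids mg/dL, NT-proBNP pg/mL, troponins ng/L); no unit inference is
performed, because silent conversion is a misclassification hazard. A
missing measurement never satisfies a criterion and never raises —
sparse panels degrade gracefully toward claims-only behavior. The
prediabetes glucose band is implemented exactly as the staging scheme
prints it, 100–124 mg/dL, although 100–125 is a common convention.

## Design decisions where the rules were genuinely open

- **Stage-1 exclusion semantics.** The stage-1 row reads "absence of
  stage 2–4 core codes". Taken literally, a single uncorroborated
  stage-2 code — or a combination code whose pairing requirement is
  unmet (I12.- with no N18.-; N18.1–N18.2 with no R80.-) — would demote
  a genuine stage-1 patient to 0, and appending claims could *lower* a
  patient's stage. The default therefore applies established-condition
  semantics: stage 1 is blocked exactly when a stage 2–4 eligibility
  fires. This makes assignment monotone under claim augmentation. The
  literal reading remains available as `strict_raw_exclusion`, which is
  the documented non-monotone exception.
- **Kidney failure without clinical CVD.** Confirmed ESRD (N18.6) or
  dialysis dependence qualifies stage 3 as a very high-risk CKD risk
  equivalent (ESRD is CKD beyond G5); with clinical CVD present the
  hierarchy assigns 4B regardless. Without this rule an ESRD patient
  with no CVD claims would stage 0, contradicting the stage-0 definition
  of "no evidence of CKD".
- **Hypertensive heart-failure combination codes.** I11.0, I13.0, and
  I13.2 sit in the heart-failure set as literals: those codes assert
  heart failure by their own semantics, so window-level co-presence of a
  separate I50.- claim is not additionally required. The I12/I13 CKD
  pairing, by contrast, is enforced at window level (claims data cannot
  guarantee same-claim pairing).
- **E78.2 expanded proxy.** Mixed hyperlipidemia is shipped in its own
  set, disabled by default via `enable_expanded_tg_proxy`; when off it is
  also removed from the stage-1 exclusion so it cannot block stage 1.
- **BMI Z-codes** (Z68.25–Z68.45) are supplementary documentation only,
  never stage-defining; likewise NAFLD/NASH, sleep-apnea, and PCOS codes
  are risk-enhancing, not stage-defining.
- **Stroke history** (I69.-, Z86.73) counts as chronic clinical CVD by
  default; `stroke_history_counts=False` supports incident-event studies.
- **Day-gap rule** ("≥2 outpatient claims on different dates, e.g. ≥30 d
  apart") treats the gap as mandatory by default; setting
  `min_day_separation=0` recovers the distinct-dates-only reading.

## Synthetic cohorts

`ckmstage.synthetic` generates claims histories with known ground truth
by construction: a stage-k patient carries claims that confirm a stage-k
core condition under the default policy (dates drawn uniformly inside the
lookback window, gaps drawn from 30–120 days) and nothing qualifying a
higher stage; stage-4 patients pair a CVD event with a confirmed stage-2
context condition; 4B adds confirmed N18.6 or a Z99.2 claim. Boundary
patients violate exactly one rule — a 29-day gap, a single outpatient
chronic claim, a confirming claim on the index date, a clinical CVD event
with no co-occurring context, or an unconfirmed single outpatient ESRD
claim — with the expected deviation recorded per patient. Measurement
panels placed exactly on the printed stage-3 thresholds are provided for
boundary-testing the EHR-enhanced criteria. Generation is deterministic
given the seed (byte-identical CSVs on re-run).

The generator emulates *structure*, not epidemiology: it does not model
realistic utilization rates, comorbidity correlations, coding noise,
miscoding, or demographic mix. Passing the recovery suite shows the
algorithm implements its stated rules exactly; it says nothing about
sensitivity or predictive value against chart review in real data, which
the framework itself leaves to future empirical validation.

## Numerical and degenerate-input choices

- Codes are validated to the ICD-10-CM shape (3–7 alphanumerics, leading
  letter); malformed codes are rejected with the offending string and CSV
  row named.
- Administrative duplicates — identical (patient, claim, date, setting,
  code) rows — collapse to one record so they cannot fabricate a second
  confirming claim; the "different dates" rule is enforced on distinct
  service dates, not claim ids.
- Care settings beyond inpatient/outpatient are rejected unless a
  `setting_map` coerces the local vocabulary.
- An empty history, an empty claims file, and a patient with only
  unrecognized codes all stage 0 with empty evidence; there is no
  "unstageable" state.
- Registry loading fails with the JSON path of the offending element;
  dangling set references name the stage and the missing set.
- With very short lookbacks (≈4 months or less) the generator's date
  placement can compress chronic gaps below threshold; cohort generation
  is intended for windows of 6 months or more (default 24).

## Problem sizes used in the shipped checks

The test suite stages a 600-patient cohort (100 per label) for exact
ground-truth recovery, runs 500 seeded claim-augmentation trials for
monotonicity, and checks matcher/oracle agreement over every registry
pattern × (all registry codes + 200 random well-formed codes). These
sizes exercise every stage row and boundary template while keeping the
whole suite in the seconds range on a single core.

## Known limitations

- The registry carries the framework's cited codes, not the complete
  ICD-10-CM tabular list; it is schema-extensible for local additions.
- No OMOP/FHIR ingestion, procedure/revenue/pharmacy data, ICD-9 or
  ICD-11 crosswalks, or code-position (primary vs secondary) logic.
- Staging is cross-sectional at one index date; longitudinal
  (worst-ever / time-updated) staging is a study-level choice outside
  scope.
- Claims-only stage 3 under-ascertains subclinical disease by design and
  should be labelled a conservative proxy in analytic use.
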