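# ckmstage

Staging engine for **cardiovascular-kidney-metabolic (CKM) syndrome** over
ICD-10-CM diagnosis claims, for epidemiologists and health-system analysts
who need reproducible CKM cohorts from administrative or EHR data.

CKM syndrome has no ICD-10-CM code of its own, so stage identification in
real-world data needs an explicit, machine-actionable operationalization.
`ckmstage` provides one: stage 0–4 code sets pinned to FY2026 ICD-10-CM
conventions, encounter-confirmation rules, and a hierarchical assignment
algorithm, applicable claims-only or EHR-enhanced.

**The model.** Each patient is staged at an index date from the claims in
a lookback window (default 24 calendar months, half-open, index date
excluded). A chronic condition is *confirmed* by ≥1 inpatient claim or
≥2 outpatient claims on different dates ≥30 days apart; an acute event
(MI, stroke) by a single inpatient claim. Stage eligibilities:

- **Stage 1** — confirmed overweight/obesity (E66.3, E66.8, E66.811–813,
  E66.9) or prediabetes (R73.03), without higher-stage disease.
- **Stage 2** — confirmed hypertension (I10, I11.9, I13.10; I12.- with
  N18.-), hypertriglyceridemia (E78.1), metabolic syndrome (E88.810),
  diabetes (E11.- incl. E11.A, E10.-, E13.-), or moderate/high-risk CKD
  (N18.30–32; N18.1–2 with R80.-).
- **Stage 3** — very high-risk CKD (N18.4–N18.5); EHR-enhanced mode adds
  subclinical atherosclerosis and heart-failure biomarker criteria and
  KDIGO very-high-risk categories, in CKM context.
- **Stage 4** — a confirmed clinical-CVD code (I21/I22, I60–I64, I25/I20,
  I50 and hypertensive-HF combinations, I48 subcodes, I70.2-/I73.9,
  I69/Z86.73) co-occurring with any stage 1–3 condition or CKD;
  **4A** without and **4B** with kidney failure (N18.6, Z99.2).

The patient receives the *highest* eligible stage (4 > 3 > 2 > 1 > 0);
stage 0 is the absence of any qualifying codes. Every assignment carries
its evidence trail. See `docs/methods.md` for the full rule semantics and
design decisions.

## Worked example

The claims-only use case: index date 2026-01-01, 24-month lookback; two
outpatient essential-hypertension claims (I10) 45 days apart, two
outpatient type-2-diabetes claims (E11.9) 60 days apart, one outpatient
obesity-class-3 claim (E66.813) with a BMI code (Z68.41), and one
inpatient acute-MI claim (I21.3); no kidney-failure codes.

```sh
ckmstage stage --claims claims.csv --index-date 2026-01-01 \
    --lookback-months 24 --out assignments.csv
```

prints the run audit to stderr and writes the assignment:

```
INFO ckmstage: staged 1 patients | mode=claims_only index=2026-01-01 lookback=24mo
  include_index_date=False min_outpatient_claims=2 min_day_separation=30d
  strict_raw_exclusion=False expanded_tg_proxy=False | counts={"4A": 1}
```

```
patient_id,stage,substage,mode,qualifying_sets
PT1,4,A,claims_only,acute_mi
```

Reading: the confirmed I10 and E11.9 establish stage 2 (established
metabolic disease); the inpatient AMI is a clinical CVD event, and with
stage-2 co-occurrence the hierarchy assigns **stage 4, substage A** —
clinical CVD without kidney failure. By contrast, a patient with only
confirmed overweight/obesity or prediabetes codes in the window is
assigned **stage 1**.

The same computation in Python:

```python
import ckmstage as ck
from datetime import date

registry = ck.default_registry()
config = ck.StagingConfig(index=ck.IndexSpec(date(2026, 1, 1), lookback_months=24))
histories = ck.read_claims("claims.csv")
assignment = ck.assign_stage(histories[0], registry, config)
assignment.stage, assignment.substage   # (4, 'A')
```

Other commands: `ckmstage simulate` writes a synthetic labelled cohort
(claims.csv, truth.csv, provenance.json) for pipeline testing;
`ckmstage validate-codesets` content-checks a registry document;
`ckmstage export` emits the registry as canonical JSON or a flattened
review CSV.

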