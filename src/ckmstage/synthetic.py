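"""Synthetic claims cohorts with known ground-truth CKM stages.

Every patient is constructed directly from the staging rules: a stage-k
patient carries claims that confirm a stage-k core condition under the
default encounter-confirmation policy (two outpatient claims >=30 days
apart, or one inpatient claim) and nothing that would qualify a higher
stage.  Boundary patients deliberately violate exactly one rule -- a
29-day gap, a single outpatient chronic claim, or a claim on the index
date -- so window and confirmation edges are exercised with a known
expected outcome.

Generation is fully deterministic given the seed: the same spec always
yields byte-identical CSV output.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .claims import ClaimRecord, IndexSpec, PatientHistory
from .ehr import MeasurementPanel
from .errors import ConfigurationError

__all__ = [
    "CohortSpec",
    "LabeledPatient",
    "STAGE_LABELS",
    "generate_patient",
    "generate_cohort",
    "cohort_to_claims_csv",
    "cohort_to_truth_csv",
    "threshold_panels",
]

STAGE_LABELS = ("0", "1", "2", "3", "4A", "4B")

# Concrete code catalogues per stage, spanning the framework's rows.
_STAGE1_CODES = ("E663", "E66811", "E66812", "E66813", "E668", "E669", "R7303")
_STAGE2_CODES = ("I10", "I119", "E781", "E88810", "E119", "E11A", "E109", "N1830", "N1831", "N1832")
_STAGE3_CODES = ("N184", "N185")
_STAGE4_ACUTE = ("I213", "I214", "I21A1", "I220", "I634", "I619", "I609")
_STAGE4_CHRONIC = ("I2510", "I209", "I501", "I509", "I480", "I4819", "I739", "Z8673")
_NOISE_CODES = ("J069", "M5450", "K5900", "A099", "H527", "L700")  # outside all CKM sets

_BOUNDARY_TEMPLATES = ("gap_29_days", "single_outpatient_claim", "index_date_claim")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``stage_mix`` maps labels 0,1,2,3,4A,4B to proportions summing to 1;
    ``boundary_fraction`` is the share of patients engineered at
    confirmation boundaries instead of cleanly satisfying their label.
    """

    n_patients: int
    stage_mix: dict[str, float] = field(
        default_factory=lambda: {k: 1 / 6 for k in STAGE_LABELS}
    )
    boundary_fraction: float = 0.0
    seed: int = 0
    index_date: date = date(2026, 1, 1)
    lookback_months: int = 24

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        unknown = set(self.stage_mix) - set(STAGE_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown stage labels in mix: {sorted(unknown)}")
        total = sum(self.stage_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"stage_mix must sum to 1, got {total}")
        if not (0.0 <= self.boundary_fraction <= 1.0):
            raise ConfigurationError("boundary_fraction must lie in [0, 1]")

    @property
    def index(self) -> IndexSpec:
        return IndexSpec(index_date=self.index_date, lookback_months=self.lookback_months)


@dataclass(frozen=True)
class LabeledPatient:
    """A synthetic history with its construction ground truth.

    ``truth_stage``/``truth_substage`` is the nominal label; for boundary
    cases ``expected_stage``/``expected_substage`` records what the
    default-configuration algorithm should actually return given the
    deliberately violated rule.
    """

    history: PatientHistory
    truth_stage: int
    truth_substage: str
    expected_stage: int
    expected_substage: str
    is_boundary_case: bool
    notes: str
    panel: Optional[MeasurementPanel] = None


def _label_parts(label: str) -> tuple[int, str]:
    if label not in STAGE_LABELS:
        raise ConfigurationError(f"unknown stage label {label!r}")
    if label in ("4A", "4B"):
        return 4, label[1]
    return int(label), "none"


class _Builder:
    """Accumulates claims for one synthetic patient."""

    def __init__(self, patient_id: str, rng: np.random.Generator, index: IndexSpec):
        self.patient_id = patient_id
        self.rng = rng
        self.index = index
        self.claims: list[ClaimRecord] = []
        self._n = 0
        lower = index.lower_bound
        # leave >=130 days of room after a start date for gap placement
        self.span_days = (index.index_date - lower).days

    def _date(self, margin: int = 130) -> date:
        hi = max(self.span_days - margin, 1)
        off = int(self.rng.integers(0, hi))
        return self.index.lower_bound + timedelta(days=off)

    def add(self, codes, setting: str, when: date) -> None:
        self._n += 1
        self.claims.append(
            ClaimRecord(
                patient_id=self.patient_id,
                claim_id=f"{self.patient_id}-C{self._n:02d}",
                service_date=when,
                setting=setting,
                codes=tuple(codes) if not isinstance(codes, str) else (codes,),
            )
        )

    def chronic_pair(self, code: str, gap_days: Optional[int] = None) -> None:
        start = self._date()
        gap = int(self.rng.integers(30, 121)) if gap_days is None else gap_days
        second = min(start + timedelta(days=gap), self.index.index_date - timedelta(days=1))
        self.add(code, "outpatient", start)
        self.add(code, "outpatient", second)

    def inpatient(self, code: str) -> None:
        self.add(code, "inpatient", self._date(margin=30))

    def noise(self, k: int = 1) -> None:
        for _ in range(k):
            code = _NOISE_CODES[int(self.rng.integers(0, len(_NOISE_CODES)))]
            self.add(code, "outpatient", self._date(margin=30))

    def history(self) -> PatientHistory:
        return PatientHistory(patient_id=self.patient_id, claims=tuple(self.claims))


def _pick(rng: np.random.Generator, options) -> str:
    return options[int(rng.integers(0, len(options)))]


def _build_clean(b: _Builder, label: str) -> str:
    """Construct claims satisfying exactly the labelled stage; returns notes."""
    rng = b.rng
    if label == "0":
        b.noise(k=int(rng.integers(1, 4)))
        return "no CKM codes"
    if label == "1":
        code = _pick(rng, _STAGE1_CODES)
        b.chronic_pair(code)
        b.noise()
        return f"confirmed adiposity/prediabetes via {code}"
    if label == "2":
        code = _pick(rng, _STAGE2_CODES)
        b.chronic_pair(code)
        b.noise()
        return f"confirmed stage-2 condition via {code}"
    if label == "3":
        code = _pick(rng, _STAGE3_CODES)
        if rng.random() < 0.5:
            b.inpatient(code)
            return f"very high-risk CKD via inpatient {code}"
        b.chronic_pair(code)
        return f"very high-risk CKD via outpatient pair {code}"
    # stage 4: clinical CVD plus a confirmed stage-2 context condition
    context = _pick(rng, ("I10", "E119", "E781"))
    b.chronic_pair(context)
    if rng.random() < 0.5:
        cvd = _pick(rng, _STAGE4_ACUTE)
        b.inpatient(cvd)
        how = f"acute inpatient {cvd}"
    else:
        cvd = _pick(rng, _STAGE4_CHRONIC)
        b.chronic_pair(cvd)
        how = f"chronic CVD pair {cvd}"
    if label == "4B":
        if rng.random() < 0.5:
            b.inpatient("N186")
            marker = "N186 inpatient"
        else:
            b.add("Z992", "outpatient", b._date(margin=30))
            marker = "Z992 presence"
        return f"{how} with context {context}; kidney failure via {marker}"
    return f"{how} with context {context}; no kidney-failure markers"


def _build_boundary(b: _Builder, label: str, template: str) -> tuple[int, str, str]:
    """Construct a boundary case; returns (expected_stage, expected_substage, notes)."""
    rng = b.rng
    stage, substage = _label_parts(label)
    if label == "4A":
        # clinical CVD with no co-occurring CKM context: stage 4 clause fails
        cvd = _pick(rng, _STAGE4_ACUTE)
        b.inpatient(cvd)
        return 0, "none", f"inpatient {cvd} without any stage 1-3 context -> 0"
    if label == "4B":
        # kidney-failure marker present but unconfirmed (single outpatient N18.6)
        _build_clean(b, "4A")
        b.add("N186", "outpatient", b._date(margin=30))
        return 4, "A", "single outpatient N186 does not confirm kidney failure -> 4A"
    code = {
        "1": _pick(rng, _STAGE1_CODES),
        "2": _pick(rng, _STAGE2_CODES),
        "3": _pick(rng, _STAGE3_CODES),
    }.get(label, "I10")
    if template == "gap_29_days":
        b.chronic_pair(code, gap_days=29)
        return 0, "none", f"two outpatient {code} 29 days apart -> unconfirmed -> 0"
    if template == "single_outpatient_claim":
        b.add(code, "outpatient", b._date(margin=30))
        return 0, "none", f"single outpatient {code} -> unconfirmed -> 0"
    # index_date_claim: second confirming claim lands on the index date,
    # outside the default half-open window
    first = b.index.index_date - timedelta(days=45)
    b.add(code, "outpatient", first)
    b.add(code, "outpatient", b.index.index_date)
    return 0, "none", f"second {code} claim on index date excluded by window -> 0"


def generate_patient(
    label: str,
    seed: int,
    index: IndexSpec | None = None,
    boundary: bool = False,
    patient_id: str | None = None,
    boundary_template: str | None = None,
) -> LabeledPatient:
    """Generate one labelled synthetic patient (deterministic given seed)."""
    stage, substage = _label_parts(label)
    index = index or IndexSpec(index_date=date(2026, 1, 1), lookback_months=24)
    rng = np.random.default_rng(seed)
    pid = patient_id or f"P{seed:08d}"
    b = _Builder(pid, rng, index)
    if boundary and label != "0":
        template = boundary_template or _BOUNDARY_TEMPLATES[seed % len(_BOUNDARY_TEMPLATES)]
        exp_stage, exp_sub, notes = _build_boundary(b, label, template)
        return LabeledPatient(
            history=b.history(),
            truth_stage=stage,
            truth_substage=substage,
            expected_stage=exp_stage,
            expected_substage=exp_sub,
            is_boundary_case=True,
            notes=f"[{template}] {notes}",
        )
    notes = _build_clean(b, label)
    return LabeledPatient(
        history=b.history(),
        truth_stage=stage,
        truth_substage=substage,
        expected_stage=stage,
        expected_substage=substage,
        is_boundary_case=False,
        notes=notes,
    )


def _rounded_counts(spec: CohortSpec) -> dict[str, int]:
    """Largest-remainder rounding of stage-mix proportions to n_patients."""
    raw = {k: spec.stage_mix.get(k, 0.0) * spec.n_patients for k in STAGE_LABELS}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = spec.n_patients - sum(counts.values())
    remainders = sorted(
        STAGE_LABELS, key=lambda k: (-(raw[k] - counts[k]), STAGE_LABELS.index(k))
    )
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def generate_cohort(spec: CohortSpec) -> list[LabeledPatient]:
    """Generate the full labelled cohort for a spec.

    Stage counts follow the mix after deterministic largest-remainder
    rounding; the first ``round(boundary_fraction * count)`` patients of
    each non-zero label are boundary cases, cycling through the boundary
    templates.
    """
    counts = _rounded_counts(spec)
    out: list[LabeledPatient] = []
    idx = 0
    for label in STAGE_LABELS:
        n_label = counts[label]
        n_boundary = int(round(spec.boundary_fraction * n_label)) if label != "0" else 0
        for j in range(n_label):
            idx += 1
            # sub-seed derived deterministically, kept well below 2**31
            sub_seed = (spec.seed * 1_000_003 + idx * 7919) % (2**31 - 1)
            out.append(
                generate_patient(
                    label,
                    seed=sub_seed,
                    index=spec.index,
                    boundary=j < n_boundary,
                    patient_id=f"P{idx:05d}",
                    boundary_template=_BOUNDARY_TEMPLATES[j % len(_BOUNDARY_TEMPLATES)],
                )
            )
    return out


def cohort_to_claims_csv(cohort: list[LabeledPatient]) -> str:
    """Serialize cohort claims in the claims CSV dialect."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["patient_id", "claim_id", "service_date", "setting", "icd10cm_code"])
    for lp in cohort:
        for claim in lp.history.claims:
            for code in claim.codes:
                w.writerow(
                    [claim.patient_id, claim.claim_id, claim.service_date.isoformat(),
                     claim.setting, code]
                )
    return buf.getvalue()


def cohort_to_truth_csv(cohort: list[LabeledPatient]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["patient_id", "truth_stage", "truth_substage", "is_boundary"])
    for lp in cohort:
        w.writerow(
            [lp.history.patient_id, lp.truth_stage, lp.truth_substage,
             str(lp.is_boundary_case).lower()]
        )
    return buf.getvalue()


def provenance_json(spec: CohortSpec) -> str:
    """Reproducibility record written alongside generated cohorts."""
    doc = {
        "n_patients": spec.n_patients,
        "stage_mix": {k: spec.stage_mix.get(k, 0.0) for k in STAGE_LABELS},
        "boundary_fraction": spec.boundary_fraction,
        "seed": spec.seed,
        "index_date": spec.index_date.isoformat(),
        "lookback_months": spec.lookback_months,
    }
    return json.dumps(doc, indent=2) + "\n"


def threshold_panels(patient_id: str = "PX") -> dict[str, MeasurementPanel]:
    """Measurement panels placed exactly on the printed stage-3 thresholds,
    for boundary testing of the EHR-enhanced criteria."""
    return {
        "ntprobnp_125": MeasurementPanel(patient_id, sex="male", ntprobnp_pg_ml=125.0),
        "ntprobnp_124": MeasurementPanel(patient_id, sex="male", ntprobnp_pg_ml=124.9),
        "hstnt_14_female": MeasurementPanel(patient_id, sex="female", hs_tnt_ng_l=14.0),
        "hstnt_14_male": MeasurementPanel(patient_id, sex="male", hs_tnt_ng_l=14.0),
        "hstnt_22_male": MeasurementPanel(patient_id, sex="male", hs_tnt_ng_l=22.0),
        "egfr_29": MeasurementPanel(patient_id, sex="male",
                                    egfr_ml_min_1_73m2=29.0, uacr_mg_g=10.0),
        "egfr_30": MeasurementPanel(patient_id, sex="male",
                                    egfr_ml_min_1_73m2=30.0, uacr_mg_g=10.0),
    }
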