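"""Structured-measurement criteria for EHR-enhanced CKM staging.

Claims data cannot see laboratory values or imaging, so the framework's
anthropometric, glycemic, biomarker, and KDIGO criteria live here and are
consulted only in EHR-enhanced mode (stage 3 especially, where subclinical
disease is defined by coronary calcification, natriuretic peptides, and
high-sensitivity troponin rather than diagnosis codes).

All threshold comparisons are inclusive, exactly as the staging scheme
prints them: BMI >=25 kg/m^2 (>=23 if Asian ancestry); waist >=88/102 cm
for women/men (>=80/90 if Asian ancestry); prediabetes as fasting glucose
100-124 mg/dL or HbA1c 5.7%-6.4%; NT-proBNP >=125 pg/mL; hs-TnT >=14 (F) /
>=22 (M) ng/L; hs-TnI >=10 (F) / >=12 (M) ng/L.  A missing measurement
never satisfies a criterion and never raises: sparse panels degrade
gracefully to claims-only behavior.

The KDIGO eGFR-albuminuria heat map ships as an editable, version-labelled
data table (``data/kdigo_grid.json``) rather than being hard-coded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources
from typing import Optional

import pandas as pd

from .errors import ClaimsFormatError, ConfigurationError

__all__ = [
    "MeasurementPanel",
    "KdigoResult",
    "adiposity_met",
    "dysfunctional_adiposity_met",
    "subclinical_hf_met",
    "subclinical_ascvd_met",
    "mets_component_count",
    "mets_met",
    "kdigo_category",
    "kdigo_grid_version",
    "read_measurements",
]

RISK_ORDER = ("low", "moderate", "high", "very_high")
G_STAGES = ("G1", "G2", "G3a", "G3b", "G4", "G5")
A_STAGES = ("A1", "A2", "A3")


@dataclass(frozen=True)
class MeasurementPanel:
    """Per-patient structured measurements; every field optional.

    Units are fixed (uACR in mg/g, eGFR in mL/min/1.73m^2, glucose and
    lipids in mg/dL, NT-proBNP in pg/mL, troponins in ng/L); no unit
    inference is performed.
    """

    patient_id: str
    sex: Optional[str] = None  # "female" | "male"
    asian_ancestry: bool = False
    bmi: Optional[float] = None
    waist_cm: Optional[float] = None
    fasting_glucose_mg_dl: Optional[float] = None
    hba1c_percent: Optional[float] = None
    ntprobnp_pg_ml: Optional[float] = None
    hs_tnt_ng_l: Optional[float] = None
    hs_tni_ng_l: Optional[float] = None
    egfr_ml_min_1_73m2: Optional[float] = None
    uacr_mg_g: Optional[float] = None
    cac_positive: Optional[bool] = None
    ct_or_cath_atherosclerosis: Optional[bool] = None
    echo_abnormal: Optional[bool] = None
    high_10yr_risk: Optional[bool] = None
    hdl_mg_dl: Optional[float] = None
    triglycerides_mg_dl: Optional[float] = None
    sbp_mmhg: Optional[float] = None
    dbp_mmhg: Optional[float] = None
    on_antihypertensives: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v < 0:
                raise ConfigurationError(f"{f.name} must be non-negative, got {v}")


@dataclass(frozen=True)
class KdigoResult:
    """KDIGO G-stage x A-stage cell and its prognosis-grid risk band."""

    g_stage: str
    a_stage: str
    risk: str

    @property
    def very_high_or_g4_g5(self) -> bool:
        """The stage-3 risk-equivalent clause: G4-G5 CKD or very high risk."""
        return self.risk == "very_high" or self.g_stage in ("G4", "G5")


def _require_sex(panel: MeasurementPanel) -> str:
    if panel.sex is None:
        raise ConfigurationError(
            f"patient {panel.patient_id!r}: sex is required to evaluate "
            "sex-specific thresholds"
        )
    return panel.sex


def adiposity_met(panel: MeasurementPanel) -> bool:
    """Excess adiposity: BMI or waist-circumference threshold met."""
    if panel.bmi is not None:
        if panel.bmi >= (23.0 if panel.asian_ancestry else 25.0):
            return True
    if panel.waist_cm is not None:
        sex = _require_sex(panel)
        if panel.asian_ancestry:
            cut = 80.0 if sex == "female" else 90.0
        else:
            cut = 88.0 if sex == "female" else 102.0
        if panel.waist_cm >= cut:
            return True
    return False


def dysfunctional_adiposity_met(panel: MeasurementPanel) -> bool:
    """Prediabetes-range glycemia: FG 100-124 mg/dL or HbA1c 5.7-6.4%."""
    fg = panel.fasting_glucose_mg_dl
    if fg is not None and 100.0 <= fg <= 124.0:
        return True
    a1c = panel.hba1c_percent
    if a1c is not None and 5.7 <= a1c <= 6.4:
        return True
    return False


def subclinical_hf_met(panel: MeasurementPanel) -> bool:
    """Elevated cardiac biomarkers and/or abnormal echocardiography."""
    if panel.ntprobnp_pg_ml is not None and panel.ntprobnp_pg_ml >= 125.0:
        return True
    if panel.hs_tnt_ng_l is not None:
        sex = _require_sex(panel)
        if panel.hs_tnt_ng_l >= (14.0 if sex == "female" else 22.0):
            return True
    if panel.hs_tni_ng_l is not None:
        sex = _require_sex(panel)
        if panel.hs_tni_ng_l >= (10.0 if sex == "female" else 12.0):
            return True
    return bool(panel.echo_abnormal)


def subclinical_ascvd_met(panel: MeasurementPanel) -> bool:
    """Coronary calcification, or atherosclerosis on CT/catheterization."""
    return bool(panel.cac_positive) or bool(panel.ct_or_cath_atherosclerosis)


def _mets_components(panel: MeasurementPanel) -> tuple[bool, bool, bool, bool, bool]:
    waist = False
    if panel.waist_cm is not None:
        sex = _require_sex(panel)
        if panel.asian_ancestry:
            waist = panel.waist_cm >= (80.0 if sex == "female" else 90.0)
        else:
            waist = panel.waist_cm >= (88.0 if sex == "female" else 102.0)
    hdl = False
    if panel.hdl_mg_dl is not None:
        sex = _require_sex(panel)
        hdl = panel.hdl_mg_dl < (40.0 if sex == "male" else 50.0)
    tg = panel.triglycerides_mg_dl is not None and panel.triglycerides_mg_dl >= 150.0
    bp = (
        (panel.sbp_mmhg is not None and panel.sbp_mmhg >= 130.0)
        or (panel.dbp_mmhg is not None and panel.dbp_mmhg >= 80.0)
        or bool(panel.on_antihypertensives)
    )
    fg = panel.fasting_glucose_mg_dl is not None and panel.fasting_glucose_mg_dl >= 100.0
    return waist, hdl, tg, bp, fg


def mets_component_count(panel: MeasurementPanel) -> int:
    """Number (0-5) of metabolic-syndrome components present."""
    return sum(_mets_components(panel))


def mets_met(panel: MeasurementPanel) -> bool:
    """Metabolic syndrome: >=3 of 5 components."""
    return mets_component_count(panel) >= 3


# ---------------------------------------------------------------------------
# KDIGO eGFR-albuminuria categorization
# ---------------------------------------------------------------------------

def _load_grid() -> dict:
    text = resources.files("ckmstage.data").joinpath("kdigo_grid.json").read_text("utf-8")
    return json.loads(text)


_GRID = _load_grid()


def kdigo_grid_version() -> str:
    return _GRID["version"]


def kdigo_category(
    egfr: Optional[float], uacr: Optional[float]
) -> Optional[KdigoResult]:
    """Classify eGFR (mL/min/1.73m^2) x uACR (mg/g) on the KDIGO grid.

    Returns ``None`` when either input is missing -- an explicit
    "not computable" outcome, never a silent default category.
    """
    if egfr is None or uacr is None:
        return None
    if egfr < 0 or uacr < 0:
        raise ConfigurationError(f"eGFR/uACR must be non-negative, got {egfr}, {uacr}")
    if egfr >= 90:
        g = "G1"
    elif egfr >= 60:
        g = "G2"
    elif egfr >= 45:
        g = "G3a"
    elif egfr >= 30:
        g = "G3b"
    elif egfr >= 15:
        g = "G4"
    else:
        g = "G5"
    if uacr < 30:
        a = "A1"
    elif uacr <= 300:
        a = "A2"
    else:
        a = "A3"
    return KdigoResult(g_stage=g, a_stage=a, risk=_GRID["risk"][g][a])


# ---------------------------------------------------------------------------
# Measurements CSV (long format)
# ---------------------------------------------------------------------------

_BOOL_FIELDS = {
    "cac_positive",
    "ct_or_cath_atherosclerosis",
    "echo_abnormal",
    "high_10yr_risk",
    "on_antihypertensives",
}
_NUMERIC_FIELDS = {
    "bmi",
    "waist_cm",
    "fasting_glucose_mg_dl",
    "hba1c_percent",
    "ntprobnp_pg_ml",
    "hs_tnt_ng_l",
    "hs_tni_ng_l",
    "egfr_ml_min_1_73m2",
    "uacr_mg_g",
    "hdl_mg_dl",
    "triglycerides_mg_dl",
    "sbp_mmhg",
    "dbp_mmhg",
}
# the CSV dialect spells the eGFR field with its conventional unit string
_FIELD_ALIASES = {"egfr_ml_min_1.73m2": "egfr_ml_min_1_73m2"}

_REQUIRED_COLUMNS = ["patient_id", "sex", "asian_ancestry", "field", "value", "date"]


def _parse_bool(raw: str, row: int) -> bool:
    v = str(raw).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ClaimsFormatError(f"row {row}: unparseable boolean {raw!r}")


def read_measurements(source) -> dict[str, MeasurementPanel]:
    """Read the long-format measurements CSV into per-patient panels.

    Header: ``patient_id,sex,asian_ancestry,field,value,date``.  When a
    field appears more than once for a patient, the most recent dated
    value wins (later row wins on a date tie).
    """
    try:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ClaimsFormatError("measurements file is empty (expected a header row)") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"measurements CSV is missing columns: {missing}")

    acc: dict[str, dict] = {}
    latest: dict[tuple[str, str], str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.patient_id)
        entry = acc.setdefault(pid, {"patient_id": pid})
        sex = str(row.sex).strip().lower()
        if sex:
            entry["sex"] = sex
        entry["asian_ancestry"] = _parse_bool(row.asian_ancestry, i)
        fname = _FIELD_ALIASES.get(str(row.field).strip(), str(row.field).strip())
        if not fname:
            continue
        when = str(row.date).strip()
        key = (pid, fname)
        if key in latest and when < latest[key]:
            continue
        latest[key] = when
        if fname in _BOOL_FIELDS:
            entry[fname] = _parse_bool(row.value, i)
        elif fname in _NUMERIC_FIELDS:
            try:
                entry[fname] = float(row.value)
            except ValueError:
                raise ClaimsFormatError(
                    f"row {i}: unparseable numeric value {row.value!r} for {fname!r}"
                ) from None
        else:
            raise ClaimsFormatError(f"row {i}: unknown measurement field {row.field!r}")
    out = {}
    for pid, entry in acc.items():
        try:
            out[pid] = MeasurementPanel(**entry)
        except ConfigurationError as err:
            raise ClaimsFormatError(f"patient {pid!r}: {err}") from None
    return out
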