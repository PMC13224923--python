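"""Patient claims histories, index dates, and lookback windowing.

Claims arrive in a long CSV dialect (one row per claim-code):

    patient_id,claim_id,service_date,setting,icd10cm_code

Rows sharing ``(patient_id, claim_id, service_date, setting)`` are grouped
into one :class:`ClaimRecord`; codes are normalized and de-duplicated so
administrative duplicates cannot fabricate extra confirming claims.  The
lookback window is the half-open interval ``[index - lookback_months,
index)`` by default; ``include_index_date`` closes the upper end for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import TYPE_CHECKING, Optional

import pandas as pd
from dateutil.relativedelta import relativedelta

from .errors import ClaimsFormatError
from .registry import normalize_code
from .errors import CodeValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .ehr import MeasurementPanel

__all__ = [
    "ClaimRecord",
    "PatientHistory",
    "IndexSpec",
    "read_claims",
    "window_claims",
    "SETTINGS",
]

SETTINGS = ("inpatient", "outpatient")


@dataclass(frozen=True)
class ClaimRecord:
    """One dated diagnosis claim with its attached ICD-10-CM codes."""

    patient_id: str
    claim_id: str
    service_date: date
    setting: str
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ClaimsFormatError(
                f"claim {self.claim_id!r}: unknown setting {self.setting!r} "
                f"(expected one of {SETTINGS})"
            )
        if not self.codes:
            raise ClaimsFormatError(f"claim {self.claim_id!r} carries no codes")
        deduped = tuple(sorted(set(self.codes)))
        if deduped != self.codes:
            object.__setattr__(self, "codes", deduped)


@dataclass(frozen=True)
class PatientHistory:
    """All claims for one patient, sorted by service date, plus an
    optional structured-measurement panel for EHR-enhanced staging."""

    patient_id: str
    claims: tuple[ClaimRecord, ...]
    measurements: Optional["MeasurementPanel"] = None

    def __post_init__(self) -> None:
        for c in self.claims:
            if c.patient_id != self.patient_id:
                raise ClaimsFormatError(
                    f"claim {c.claim_id!r} belongs to {c.patient_id!r}, "
                    f"not {self.patient_id!r}"
                )
        ordered = tuple(
            sorted(self.claims, key=lambda c: (c.service_date, c.claim_id, c.setting))
        )
        if ordered != self.claims:
            object.__setattr__(self, "claims", ordered)


@dataclass(frozen=True)
class IndexSpec:
    """Index date and lookback window definition.

    The window is ``[index_date - lookback_months, index_date)``: claims on
    the index date itself are excluded from baseline staging unless
    ``include_index_date`` is set.  Months are calendar months (same
    day-of-month, clamped to month end), not 30-day blocks.
    """

    index_date: date
    lookback_months: int = 24
    include_index_date: bool = False

    def __post_init__(self) -> None:
        if self.lookback_months < 1:
            raise ClaimsFormatError(
                f"lookback_months must be positive, got {self.lookback_months}"
            )

    @property
    def lower_bound(self) -> date:
        return self.index_date - relativedelta(months=self.lookback_months)

    def contains(self, d: date) -> bool:
        if d < self.lower_bound:
            return False
        if self.include_index_date:
            return d <= self.index_date
        return d < self.index_date


def window_claims(history: PatientHistory, index: IndexSpec) -> PatientHistory:
    """Retain exactly the claims inside the lookback window (idempotent)."""
    kept = tuple(c for c in history.claims if index.contains(c.service_date))
    return replace(history, claims=kept)


_REQUIRED_COLUMNS = ["patient_id", "claim_id", "service_date", "setting", "icd10cm_code"]


def read_claims(
    source,
    setting_map: Optional[dict[str, str]] = None,
) -> list[PatientHistory]:
    """Read a claims CSV into per-patient histories.

    Parameters
    ----------
    source
        Path or file-like object holding the claims CSV.
    setting_map
        Optional coercion of local care-setting vocabularies onto
        ``inpatient``/``outpatient`` (e.g., ``{"emergency": "inpatient"}``).
        Unmapped unknown settings are rejected with the row number.

    Returns
    -------
    list of PatientHistory, sorted by patient id; rows grouped into claims
    by (patient_id, claim_id, service_date, setting).  The result is
    invariant to input row order.
    """
    try:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ClaimsFormatError("claims file is empty (expected a header row)") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"claims CSV is missing columns: {missing}")
    if df.empty:
        return []

    setting_map = setting_map or {}
    records: dict[tuple[str, str, date, str], set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        setting = str(row.setting).strip().lower()
        setting = setting_map.get(setting, setting)
        if setting not in SETTINGS:
            raise ClaimsFormatError(f"row {i}: unknown setting {row.setting!r}")
        try:
            svc = date.fromisoformat(str(row.service_date).strip())
        except ValueError:
            raise ClaimsFormatError(
                f"row {i}: unparseable service_date {row.service_date!r} "
                "(expected YYYY-MM-DD)"
            ) from None
        try:
            code = normalize_code(row.icd10cm_code)
        except CodeValidationError as err:
            raise ClaimsFormatError(f"row {i}: {err}") from None
        key = (str(row.patient_id), str(row.claim_id), svc, setting)
        records.setdefault(key, set()).add(code)

    by_patient: dict[str, list[ClaimRecord]] = {}
    for (pid, cid, svc, setting), codes in records.items():
        by_patient.setdefault(pid, []).append(
            ClaimRecord(
                patient_id=pid,
                claim_id=cid,
                service_date=svc,
                setting=setting,
                codes=tuple(sorted(codes)),
            )
        )
    return [
        PatientHistory(patient_id=pid, claims=tuple(claims))
        for pid, claims in sorted(by_patient.items())
    ]
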