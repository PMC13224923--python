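"""Encounter-confirmation rules for code-set-defined conditions.

A chronic condition (hypertension, diabetes, CKD, obesity, ...) counts as
confirmed within the lookback window when it appears on at least one
inpatient claim, or on >=2 outpatient claims on different dates with at
least one pair of those dates >=30 days apart (all thresholds tunable via
:class:`ConfirmationPolicy`).  An acute event (myocardial infarction,
stroke) is confirmed by a single inpatient claim.  The 30-day boundary is
inclusive: exactly 30 days apart confirms under the default policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .claims import PatientHistory
from .errors import ConfigurationError
from .registry import CodeSet

__all__ = ["ConfirmationPolicy", "ConditionStatus", "confirm_condition", "raw_presence"]


@dataclass(frozen=True)
class ConfirmationPolicy:
    """Tunable claim-count and day-gap thresholds for ascertainment."""

    min_outpatient_claims: int = 2
    min_day_separation: int = 30
    inpatient_sufficient: bool = True
    acute_single_inpatient: bool = True

    def __post_init__(self) -> None:
        if self.min_outpatient_claims < 1:
            raise ConfigurationError(
                f"min_outpatient_claims must be >=1, got {self.min_outpatient_claims}"
            )
        if self.min_day_separation < 0:
            raise ConfigurationError(
                f"min_day_separation must be >=0, got {self.min_day_separation}"
            )


@dataclass(frozen=True)
class ConditionStatus:
    """Outcome of ascertaining one code set for one (windowed) patient.

    ``evidence`` lists every (service date, setting, matched code) that
    contributed; ``basis`` records which rule fired (``inpatient``,
    ``outpatient_pair``, ``acute_event``, or ``none``).
    """

    set_name: str
    confirmed: bool
    basis: str
    evidence: tuple[tuple[date, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.confirmed and (not self.evidence or self.basis == "none"):
            raise ConfigurationError(
                f"confirmed status for {self.set_name!r} requires evidence and a basis"
            )


def _matched_evidence(history: PatientHistory, code_set: CodeSet):
    """Per-claim matches: (claim, matched codes) for claims hitting the set."""
    out = []
    for claim in history.claims:
        hits = tuple(c for c in claim.codes if code_set.matches(c))
        if hits:
            out.append((claim, hits))
    return out


def _evidence_rows(matched) -> tuple[tuple[date, str, str], ...]:
    rows = []
    for claim, hits in matched:
        for code in hits:
            rows.append((claim.service_date, claim.setting, code))
    return tuple(rows)


def confirm_condition(
    history: PatientHistory,
    code_set: CodeSet,
    policy: ConfirmationPolicy = ConfirmationPolicy(),
) -> ConditionStatus:
    """Apply the chronic/acute confirmation rule to one code set.

    ``history`` must already be windowed.  Inpatient evidence takes
    precedence over an outpatient pair when both would confirm, so the
    reported basis is deterministic.
    """
    matched = _matched_evidence(history, code_set)
    inpatient = [(c, h) for c, h in matched if c.setting == "inpatient"]
    outpatient = [(c, h) for c, h in matched if c.setting == "outpatient"]

    if code_set.acuity == "acute":
        if policy.acute_single_inpatient and inpatient:
            return ConditionStatus(
                code_set.name, True, "acute_event", _evidence_rows(inpatient)
            )
        return ConditionStatus(code_set.name, False, "none")

    if policy.inpatient_sufficient and inpatient:
        return ConditionStatus(code_set.name, True, "inpatient", _evidence_rows(matched))

    dates = sorted({c.service_date for c, _ in outpatient})
    if (
        len(dates) >= policy.min_outpatient_claims
        and dates
        and (dates[-1] - dates[0]).days >= policy.min_day_separation
    ):
        return ConditionStatus(
            code_set.name, True, "outpatient_pair", _evidence_rows(outpatient)
        )
    return ConditionStatus(code_set.name, False, "none")


def raw_presence(history: PatientHistory, code_set: CodeSet) -> bool:
    """True iff any claim in the (windowed) history carries a matching
    code, with no claim-count or setting requirement."""
    return any(code_set.matches(c) for claim in history.claims for c in claim.codes)
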