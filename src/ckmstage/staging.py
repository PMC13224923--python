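"""Hierarchical CKM stage assignment (4 > 3 > 2 > 1 > 0).

Each stage has an eligibility predicate built from confirmed conditions
(:mod:`ckmstage.ascertainment`) and raw code presence; the patient is
assigned the highest stage whose predicate holds, stage 0 being the
absence of any qualifying codes.  Stage 4 splits into 4A (no kidney
failure) and 4B (ESRD N18.6 confirmed and/or dialysis dependence Z99.2
present).

Two operating modes exist.  ``claims_only`` stages from diagnosis codes
alone; its stage 3 is a conservative proxy limited to very high-risk CKD
(N18.4-N18.5).  ``ehr_enhanced`` additionally admits stage 3 through
structured measurements (subclinical atherosclerosis, subclinical heart
failure biomarkers, KDIGO very-high risk, or an externally supplied
high 10-year-risk flag), provided the patient has CKM context -- a
confirmed stage 1/2 core condition or any CKD code in the window.  The
two modes can only differ through stage-3 eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ascertainment import ConditionStatus, ConfirmationPolicy, confirm_condition, raw_presence
from .claims import IndexSpec, PatientHistory, window_claims
from .ehr import MeasurementPanel, kdigo_category, subclinical_ascvd_met, subclinical_hf_met
from .errors import ConfigurationError
from .registry import CodePattern, CodeSet, Registry

__all__ = [
    "StagingConfig",
    "StageAssignment",
    "assign_stage",
    "eligible_stage1",
    "eligible_stage2",
    "eligible_stage3",
    "eligible_stage4",
    "ckd_moderate_high",
    "substage_stage4",
    "MODES",
]

MODES = ("claims_only", "ehr_enhanced")

# Engine-internal code-set names; the shipped registry defines them, and a
# custom registry must preserve these names for the stage predicates.
S1_CORE = ("overweight_obesity", "prediabetes")
HYPERTENSION_PLAIN = "hypertension"
HYPERTENSIVE_CKD = "hypertensive_ckd"
TG_SET = "hypertriglyceridemia"
TG_EXPANDED_SET = "hypertriglyceridemia_expanded"
METS_SET = "metabolic_syndrome"
DIABETES_SET = "diabetes"
CKD_MODERATE_SET = "ckd_stage3_moderate"
CKD_STAGE12_SET = "ckd_stage12"
ALBUMINURIA_SET = "albuminuria_proteinuria"
CKD_VERY_HIGH_SET = "ckd_very_high_risk"
KIDNEY_FAILURE_SET = "kidney_failure"
KIDNEY_TRANSPLANT_SET = "kidney_transplant"

# Any-CKD presence (the "and/or CKD" context clause) is a fixed family
# probe, not a registry set, so that N18 codes classify only to the stage
# rows that own them.
_CKD_FAMILY = CodeSet(
    name="_ckd_any", role="supplementary", acuity="chronic",
    patterns=(CodePattern("family", "N18"),),
)


@dataclass(frozen=True)
class StagingConfig:
    """Run-level knobs for the staging algorithm."""

    mode: str = "claims_only"
    policy: ConfirmationPolicy = field(default_factory=ConfirmationPolicy)
    index: IndexSpec = None  # type: ignore[assignment]
    strict_raw_exclusion: bool = False
    enable_expanded_tg_proxy: bool = False
    transplant_as_kidney_failure: bool = False
    stroke_history_counts: bool = True
    measurements_enabled: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.index is None:
            raise ConfigurationError("StagingConfig requires an IndexSpec")
        if self.mode == "ehr_enhanced" and not self.measurements_enabled:
            raise ConfigurationError(
                "ehr_enhanced mode requires the measurements channel "
                "(set measurements_enabled=True and supply panels)"
            )


@dataclass(frozen=True)
class StageAssignment:
    """Final stage for one patient with the qualifying evidence trail."""

    patient_id: str
    stage: int
    substage: str  # "none" | "A" | "B"
    mode: str
    eligibilities: dict[int, bool]
    evidence: dict[int, tuple[ConditionStatus, ...]]

    def __post_init__(self) -> None:
        if (self.stage == 4) != (self.substage in ("A", "B")):
            raise ConfigurationError("substage A/B if and only if stage 4")
        expected = max((k for k, v in self.eligibilities.items() if v), default=0)
        if self.stage != expected:
            raise ConfigurationError(
                f"stage {self.stage} does not equal highest eligible stage {expected}"
            )

    @property
    def qualifying_sets(self) -> tuple[str, ...]:
        if self.stage == 0:
            return ()
        return tuple(s.set_name for s in self.evidence.get(self.stage, ()))


def _compute_statuses(
    windowed: PatientHistory, registry: Registry, policy: ConfirmationPolicy
) -> dict[str, ConditionStatus]:
    return {
        cs.name: confirm_condition(windowed, cs, policy) for cs in registry.code_sets
    }


def _stage2_core_names(registry: Registry, config: StagingConfig) -> tuple[str, ...]:
    names = registry.stage(2).core_sets
    if not config.enable_expanded_tg_proxy:
        names = tuple(n for n in names if n != TG_EXPANDED_SET)
    return names


def ckd_moderate_high(
    statuses: dict[str, ConditionStatus], windowed: PatientHistory, registry: Registry
) -> bool:
    """Moderate- to high-risk CKD claims proxy.

    CKD stage 3 (N18.30-N18.32) confirmed, or CKD stage 1-2 (N18.1-N18.2)
    confirmed together with an albuminuria/proteinuria code (R80.-)
    present in the window.  Forced false when very high-risk CKD or
    kidney failure is confirmed -- those route to stages 3 and 4B.
    """
    if statuses[CKD_VERY_HIGH_SET].confirmed or statuses[KIDNEY_FAILURE_SET].confirmed:
        return False
    if statuses[CKD_MODERATE_SET].confirmed:
        return True
    return statuses[CKD_STAGE12_SET].confirmed and raw_presence(
        windowed, registry.code_set(ALBUMINURIA_SET)
    )


def eligible_stage2(
    statuses: dict[str, ConditionStatus],
    windowed: PatientHistory,
    registry: Registry,
    config: StagingConfig,
) -> bool:
    """Metabolic risk factors or moderate/high-risk CKD.

    Hypertensive-CKD combination codes (I12.-) qualify only with an N18
    code in the window, per the coding convention that pairs them.
    """
    if statuses[HYPERTENSION_PLAIN].confirmed:
        return True
    if statuses[HYPERTENSIVE_CKD].confirmed and raw_presence(windowed, _CKD_FAMILY):
        return True
    if statuses[TG_SET].confirmed:
        return True
    if config.enable_expanded_tg_proxy and statuses[TG_EXPANDED_SET].confirmed:
        return True
    if statuses[METS_SET].confirmed or statuses[DIABETES_SET].confirmed:
        return True
    return ckd_moderate_high(statuses, windowed, registry)


def eligible_stage1(
    statuses: dict[str, ConditionStatus],
    windowed: PatientHistory,
    registry: Registry,
    config: StagingConfig,
    panel: MeasurementPanel | None = None,
) -> bool:
    """Excess/dysfunctional adiposity without higher-stage disease.

    Qualifies through confirmed overweight/obesity or prediabetes.  By
    default the block applies established-condition semantics: stage 1 is
    excluded exactly when a stage 2-4 eligibility fires, so a single
    uncorroborated stage-2 code -- or a combination code whose pairing
    requirement is unmet (I12.- with no N18.-, N18.1-N18.2 with no
    R80.-) -- does not demote a genuine stage-1 patient to 0.
    ``strict_raw_exclusion`` switches to the literal reading: any raw
    stage 2-4 core code in the window excludes stage 1.
    """
    if not any(statuses[n].confirmed for n in registry.stage(1).core_sets):
        return False
    if config.strict_raw_exclusion:
        exclusion_names = registry.stage(1).exclusion_sets
        if not config.enable_expanded_tg_proxy:
            exclusion_names = tuple(n for n in exclusion_names if n != TG_EXPANDED_SET)
        return not any(
            raw_presence(windowed, registry.code_set(n)) for n in exclusion_names
        )
    return not (
        eligible_stage2(statuses, windowed, registry, config)
        or eligible_stage3(statuses, windowed, registry, config, panel)
        or eligible_stage4(statuses, windowed, registry, config)
    )


def eligible_stage3(
    statuses: dict[str, ConditionStatus],
    windowed: PatientHistory,
    registry: Registry,
    config: StagingConfig,
    panel: MeasurementPanel | None,
) -> bool:
    """Subclinical CVD or risk equivalents, in CKM context.

    Claims-only: confirmed very high-risk CKD (N18.4-N18.5); no further
    context is required because very high-risk CKD is itself CKD.
    Confirmed kidney failure (ESRD N18.6 / dialysis dependence) likewise
    qualifies as a risk equivalent -- it is CKD beyond G5 -- so an ESRD
    patient without clinical CVD stages as 3 rather than falling through
    to 0/1 (with CVD the hierarchy assigns 4B regardless).
    EHR-enhanced additionally: (subclinical ASCVD or subclinical HF or
    KDIGO very-high/G4-G5 or external high 10-year-risk flag) and CKM
    context (a confirmed stage 1/2 core condition or any CKD code).
    """
    if statuses[CKD_VERY_HIGH_SET].confirmed or statuses[KIDNEY_FAILURE_SET].confirmed:
        return True
    if config.mode != "ehr_enhanced" or panel is None:
        return False
    kdigo = kdigo_category(panel.egfr_ml_min_1_73m2, panel.uacr_mg_g)
    risk_equivalent = (
        subclinical_ascvd_met(panel)
        or subclinical_hf_met(panel)
        or (kdigo is not None and kdigo.very_high_or_g4_g5)
        or bool(panel.high_10yr_risk)
    )
    if not risk_equivalent:
        return False
    context = (
        any(statuses[n].confirmed for n in registry.stage(1).core_sets)
        or eligible_stage2(statuses, windowed, registry, config)
        or raw_presence(windowed, _CKD_FAMILY)
    )
    return context


def eligible_stage4(
    statuses: dict[str, ConditionStatus],
    windowed: PatientHistory,
    registry: Registry,
    config: StagingConfig,
) -> bool:
    """Clinical CVD co-occurring with any stage 1-3 core condition or CKD."""
    cvd_names = registry.stage(4).core_sets
    if not config.stroke_history_counts:
        cvd_names = tuple(n for n in cvd_names if n != "stroke_history")
    if not any(statuses[n].confirmed for n in cvd_names):
        return False
    context = (
        any(statuses[n].confirmed for n in registry.stage(1).core_sets)
        or eligible_stage2(statuses, windowed, registry, config)
        or statuses[CKD_VERY_HIGH_SET].confirmed
        or raw_presence(windowed, _CKD_FAMILY)
    )
    return context


def substage_stage4(
    statuses: dict[str, ConditionStatus],
    windowed: PatientHistory,
    registry: Registry,
    config: StagingConfig,
) -> str:
    """4B when kidney failure is present: ESRD (N18.6) confirmed and/or
    dialysis dependence (Z99.2) present; optionally transplant status
    (Z94.0) with any N18 code."""
    if statuses[KIDNEY_FAILURE_SET].confirmed:
        return "B"
    kf = registry.code_set(KIDNEY_FAILURE_SET)
    z992 = CodeSet("_z992", "substage_marker", "chronic",
                   tuple(p for p in kf.patterns if p.value == "Z992") or kf.patterns)
    if any(p.value == "Z992" for p in kf.patterns) and raw_presence(windowed, z992):
        return "B"
    if config.transplant_as_kidney_failure:
        if raw_presence(windowed, registry.code_set(KIDNEY_TRANSPLANT_SET)) and raw_presence(
            windowed, _CKD_FAMILY
        ):
            return "B"
    return "A"


def _stage_evidence(
    stage: int,
    statuses: dict[str, ConditionStatus],
    registry: Registry,
    config: StagingConfig,
) -> tuple[ConditionStatus, ...]:
    """The confirmed ConditionStatuses that qualified a stage."""
    if stage == 0:
        return ()
    names = registry.stage(stage).core_sets
    if stage == 2:
        names = _stage2_core_names(registry, config)
    if stage == 3:
        names = names + (KIDNEY_FAILURE_SET,)
    if stage == 4 and not config.stroke_history_counts:
        names = tuple(n for n in names if n != "stroke_history")
    return tuple(statuses[n] for n in names if statuses[n].confirmed)


def assign_stage(
    history: PatientHistory,
    registry: Registry,
    config: StagingConfig,
) -> StageAssignment:
    """Window the claims, ascertain every code set once, evaluate the four
    stage predicates, and return the highest qualifying stage."""
    windowed = window_claims(history, config.index)
    panel = history.measurements if config.mode == "ehr_enhanced" else None
    statuses = _compute_statuses(windowed, registry, config.policy)

    eligibilities = {
        1: eligible_stage1(statuses, windowed, registry, config, panel),
        2: eligible_stage2(statuses, windowed, registry, config),
        3: eligible_stage3(statuses, windowed, registry, config, panel),
        4: eligible_stage4(statuses, windowed, registry, config),
    }
    stage = max((k for k, v in eligibilities.items() if v), default=0)
    substage = (
        substage_stage4(statuses, windowed, registry, config) if stage == 4 else "none"
    )
    evidence = {
        k: _stage_evidence(k, statuses, registry, config)
        for k, v in eligibilities.items()
        if v
    }
    return StageAssignment(
        patient_id=history.patient_id,
        stage=stage,
        substage=substage,
        mode=config.mode,
        eligibilities=eligibilities,
        evidence=evidence,
    )
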