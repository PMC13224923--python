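"""Stage-eligibility predicates and the hierarchical assignment."""

from dataclasses import replace
from datetime import date

import numpy as np
import pytest

import ckmstage as ck
from ckmstage.errors import ConfigurationError
from ckmstage.staging import (
    ckd_moderate_high,
    eligible_stage1,
    eligible_stage2,
    eligible_stage3,
    eligible_stage4,
)
from ckmstage.synthetic import STAGE_LABELS, generate_patient

from conftest import make_history


def _assign(history, registry, **kwargs):
    index = kwargs.pop("index", ck.IndexSpec(date(2026, 1, 1), 24))
    cfg = ck.StagingConfig(index=index, **kwargs)
    return ck.assign_stage(history, registry, cfg)


def pair(code, d1="2025-03-01", d2="2025-04-15", pid="P"):
    return [
        ("a", d1, "outpatient", [code]),
        ("b", d2, "outpatient", [code]),
    ]


class TestWorkedExample:
    def test_use_case_patient_is_stage_4a(self, registry, worked_example_history):
        """Confirmed hypertension and diabetes qualify stage 2; the
        inpatient AMI is a clinical CVD event; the hierarchy assigns 4A
        (clinical CVD without kidney failure)."""
        a = _assign(worked_example_history, registry)
        assert (a.stage, a.substage) == (4, "A")
        assert a.eligibilities[2] and a.eligibilities[4]
        assert not a.eligibilities[1]
        assert "acute_mi" in a.qualifying_sets

    def test_contrast_patient_is_stage_1(self, registry, contrast_history):
        a = _assign(contrast_history, registry)
        assert (a.stage, a.substage) == (1, "none")

    def test_empty_history_is_stage_0(self, registry):
        a = _assign(ck.PatientHistory("P", ()), registry)
        assert (a.stage, a.substage) == (0, "none")
        assert a.qualifying_sets == ()


class TestStage1:
    def test_confirmed_obesity_alone_qualifies(self, registry):
        assert _assign(make_history("P", pair("E669")), registry).stage == 1

    def test_confirmed_prediabetes_alone_qualifies(self, registry):
        assert _assign(make_history("P", pair("R7303")), registry).stage == 1

    def test_confirmed_hypertension_blocks_stage1(self, registry):
        rows = pair("R7303") + [
            ("c", "2025-05-01", "outpatient", ["I10"]),
            ("d", "2025-06-15", "outpatient", ["I10"]),
        ]
        a = _assign(make_history("P", rows), registry)
        assert not a.eligibilities[1]
        assert a.stage == 2

    def test_bmi_code_alone_is_never_stage_defining(self, registry):
        assert _assign(make_history("P", pair("Z6827")), registry).stage == 0

    def test_single_uncorroborated_stage2_code_does_not_demote(self, registry):
        rows = pair("E669") + [("c", "2025-05-01", "outpatient", ["I10"])]
        assert _assign(make_history("P", rows), registry).stage == 1

    def test_strict_raw_exclusion_demotes_on_presence(self, registry):
        rows = pair("E669") + [("c", "2025-05-01", "outpatient", ["I10"])]
        a = _assign(make_history("P", rows), registry, strict_raw_exclusion=True)
        assert a.stage == 0


class TestStage2:
    @pytest.mark.parametrize("code", ["I10", "I119", "I1310", "E781", "E88810",
                                      "E119", "E11A", "E109", "E139", "N1831"])
    def test_each_core_condition_qualifies(self, registry, code):
        assert _assign(make_history("P", pair(code)), registry).stage == 2

    def test_expanded_tg_proxy_gates_e782(self, registry):
        h = make_history("P", pair("E782"))
        assert _assign(h, registry).stage == 0
        assert _assign(h, registry, enable_expanded_tg_proxy=True).stage == 2

    def test_supplementary_nafld_is_not_stage_defining(self, registry):
        assert _assign(make_history("P", pair("K760")), registry).stage == 0

    def test_hypertensive_ckd_needs_n18_in_window(self, registry):
        h = make_history("P", pair("I129"))
        assert _assign(h, registry).stage == 0
        rows = pair("I129") + [("c", "2025-05-01", "outpatient", ["N183"])]
        assert _assign(make_history("P", rows), registry).stage == 2

    def test_ckd_stage12_needs_albuminuria_code(self, registry):
        h = make_history("P", pair("N182"))
        assert _assign(h, registry).stage == 0
        rows = pair("N182") + [("c", "2025-05-01", "outpatient", ["R809"])]
        assert _assign(make_history("P", rows), registry).stage == 2

    def test_very_high_risk_ckd_routes_to_stage3_not_2(self, registry):
        a = _assign(make_history("P", pair("N184")), registry)
        assert a.stage == 3
        assert not a.eligibilities[2]


class TestStage3:
    def test_confirmed_n185_claims_only(self, registry):
        assert _assign(make_history("P", pair("N185")), registry).stage == 3

    def _ehr(self, registry, rows, panel, **kwargs):
        h = make_history("P", rows)
        h = replace(h, measurements=panel)
        return _assign(h, registry, mode="ehr_enhanced",
                       measurements_enabled=True, **kwargs)

    def test_cac_flag_with_obesity_context(self, registry):
        panel = ck.MeasurementPanel("P", sex="male", cac_positive=True)
        a = self._ehr(registry, pair("E669"), panel)
        assert a.stage == 3

    def test_cac_flag_without_context_does_not_qualify(self, registry):
        panel = ck.MeasurementPanel("P", sex="male", cac_positive=True)
        a = self._ehr(registry, [], panel)
        assert a.stage == 0

    def test_kdigo_very_high_with_context(self, registry):
        panel = ck.MeasurementPanel("P", sex="male",
                                    egfr_ml_min_1_73m2=25.0, uacr_mg_g=10.0)
        assert self._ehr(registry, pair("E669"), panel).stage == 3

    def test_high_10yr_risk_flag_with_context(self, registry):
        panel = ck.MeasurementPanel("P", sex="male", high_10yr_risk=True)
        assert self._ehr(registry, pair("I10"), panel).stage == 3

    def test_measurements_never_consulted_in_claims_only(self, registry):
        panel = ck.MeasurementPanel("P", sex="male", cac_positive=True)
        h = replace(make_history("P", pair("E669")), measurements=panel)
        a = _assign(h, registry)  # claims_only
        assert a.stage == 1

    def test_ehr_mode_requires_measurements_channel(self):
        with pytest.raises(ConfigurationError):
            ck.StagingConfig(mode="ehr_enhanced",
                             index=ck.IndexSpec(date(2026, 1, 1), 24))


class TestStage4:
    def test_inpatient_ami_with_confirmed_htn(self, registry):
        rows = pair("I10") + [("c", "2025-08-20", "inpatient", ["I213"])]
        a = _assign(make_history("P", rows), registry)
        assert (a.stage, a.substage) == (4, "A")

    def test_inpatient_ami_alone_fails_cooccurrence(self, registry):
        rows = [("c", "2025-08-20", "inpatient", ["I213"])]
        a = _assign(make_history("P", rows), registry)
        assert not a.eligibilities[4]
        assert a.stage == 0

    def test_heart_failure_with_ckd_presence(self, registry):
        rows = pair("I509") + [("c", "2025-05-01", "outpatient", ["N183"])]
        a = _assign(make_history("P", rows), registry)
        assert (a.stage, a.substage) == (4, "A")

    def test_chronic_cvd_needs_two_claims(self, registry):
        rows = pair("I10") + [("c", "2025-08-20", "outpatient", ["I2510"])]
        assert _assign(make_history("P", rows), registry).stage == 2

    def test_stroke_history_counts_unless_disabled(self, registry):
        rows = pair("I10") + pair("Z8673", d1="2025-06-01", d2="2025-08-01")
        rows = [(f"r{i}",) + r[1:] for i, r in enumerate(rows)]
        h = make_history("P", rows)
        assert _assign(h, registry).stage == 4
        assert _assign(h, registry, stroke_history_counts=False).stage == 2

    def test_substage_b_via_confirmed_esrd(self, registry):
        rows = pair("I10") + [
            ("c", "2025-08-20", "inpatient", ["I213"]),
            ("d", "2025-09-01", "inpatient", ["N186"]),
        ]
        a = _assign(make_history("P", rows), registry)
        assert (a.stage, a.substage) == (4, "B")

    def test_substage_b_via_dialysis_presence(self, registry):
        rows = pair("I10") + [
            ("c", "2025-08-20", "inpatient", ["I213"]),
            ("d", "2025-09-01", "outpatient", ["Z992"]),
        ]
        a = _assign(make_history("P", rows), registry)
        assert (a.stage, a.substage) == (4, "B")

    def test_single_outpatient_esrd_claim_stays_4a(self, registry):
        rows = pair("I10") + [
            ("c", "2025-08-20", "inpatient", ["I213"]),
            ("d", "2025-09-01", "outpatient", ["N186"]),
        ]
        a = _assign(make_history("P", rows), registry)
        assert (a.stage, a.substage) == (4, "A")

    def test_transplant_substage_is_config_gated(self, registry):
        rows = pair("I10") + [
            ("c", "2025-08-20", "inpatient", ["I213"]),
            ("d", "2025-09-01", "outpatient", ["Z940", "N183"]),
        ]
        h = make_history("P", rows)
        assert _assign(h, registry).substage == "A"
        assert _assign(h, registry, transplant_as_kidney_failure=True).substage == "B"


class TestHierarchyProperties:
    def test_reported_stage_is_max_eligible(self, registry, worked_example_history):
        a = _assign(worked_example_history, registry)
        assert a.stage == max(k for k, v in a.eligibilities.items() if v)

    def test_stage1_excludes_confirmed_higher_core(self, registry):
        """Mutual-exclusion audit over a synthetic cohort: whenever stage 1
        is reported, no stage 2-4 core condition is confirmed."""
        cfg = ck.StagingConfig(index=ck.IndexSpec(date(2026, 1, 1), 24))
        for seed in range(40):
            lp = generate_patient("1", seed=seed)
            a = ck.assign_stage(lp.history, registry, cfg)
            if a.stage == 1:
                assert not any(a.eligibilities[k] for k in (2, 3, 4))

    def test_windowing_applied_before_staging(self, registry):
        rows = pair("I10", d1="2022-03-01", d2="2022-04-15")  # before lookback
        assert _assign(make_history("P", rows), registry).stage == 0

    @pytest.mark.parametrize("trials", [200])
    def test_monotonicity_under_claim_augmentation(self, registry, trials):
        """Appending claims never lowers the assigned stage under the
        default configuration."""
        rng = np.random.default_rng(2024)
        index = ck.IndexSpec(date(2026, 1, 1), 24)
        cfg = ck.StagingConfig(index=index)
        extra_codes = ["I10", "E119", "E669", "N184", "I213", "I509", "N186",
                       "Z992", "R7303", "E781", "J069", "N183", "R809"]
        for t in range(trials):
            label = STAGE_LABELS[int(rng.integers(0, len(STAGE_LABELS)))]
            lp = generate_patient(label, seed=int(rng.integers(0, 2**31 - 1)))
            before = ck.assign_stage(lp.history, registry, cfg).stage
            code = extra_codes[int(rng.integers(0, len(extra_codes)))]
            setting = "inpatient" if rng.random() < 0.3 else "outpatient"
            day = index.lower_bound + np.timedelta64(int(rng.integers(0, 700)), "D")
            extra = ck.ClaimRecord(
                lp.history.patient_id, f"aug{t}",
                day.astype("datetime64[D]").item() if hasattr(day, "astype") else day,
                setting, (code,),
            )
            augmented = replace(lp.history, claims=lp.history.claims + (extra,))
            after = ck.assign_stage(augmented, registry, cfg).stage
            assert after >= before, (
                f"stage dropped {before}->{after} adding {code}/{setting} "
                f"to {label} patient (trial {t})"
            )
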