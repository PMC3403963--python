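"""Eligibility cascade: SIRS, organ dysfunction, high risk, temporal
rule, population labels, and the imputation rules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sepsispgx.cohort import (
    CohortInfo,
    OrganDysfunctionProfile,
    OrganSystemEntry,
    PatientRecord,
    SIRSProfile,
)
from sepsispgx.config import StudyConfig
from sepsispgx.errors import ConfigurationError
from sepsispgx.screen import (
    POP_EXCLUDED,
    POP_INDICATED,
    POP_NON_INDICATED,
    assess_high_risk,
    assess_organ_dysfunction,
    assess_sirs,
    classify_population,
    impute_matching_variables,
    months_before,
    temporal_eligibility,
)

D = dt.date


def make_record(**overrides) -> PatientRecord:
    base = dict(
        patient_id="P1",
        cohort_id="c1",
        center_id="ctr1",
        age=60.0,
        sex="male",
        enrollment_date=D(2004, 6, 1),
        treated="control",
        severity_score_type="APACHE2",
        severity_score=26,
        medical_surgical="medical",
        ventilated="yes",
        infection_site="lung",
        infection_suspected=True,
        platelets=120_000.0,
        daa_status_known=True,
        sirs=SIRSProfile(temperature=39.0, heart_rate=110, resp_rate=28, wbc=15_000),
        organ_dysfunction=OrganDysfunctionProfile(
            systems={
                "cardiovascular": OrganSystemEntry(True, D(2004, 6, 1)),
                "pulmonary": OrganSystemEntry(True, D(2004, 6, 2)),
                "cns": OrganSystemEntry(False),
                "coagulation": OrganSystemEntry(False),
                "renal": OrganSystemEntry(False),
                "hepatic": OrganSystemEntry(False),
            },
            vasopressor_use=True,
            pao2_fio2=250.0,
        ),
    )
    base.update(overrides)
    return PatientRecord(**base)


COHORT = CohortInfo("c1", "ctr1", None, D(2003, 1, 1), "APACHE2")


class TestSIRS:
    @pytest.mark.parametrize(
        "profile, expected_count, expected_met",
        [
            # two of four: HR > 90 and RR > 20
            (SIRSProfile(temperature=37.0, heart_rate=95, resp_rate=22, wbc=9_000), 2, True),
            # boundary temperature 36.0 is NOT abnormal (strict <36)
            (SIRSProfile(temperature=36.0, heart_rate=80, resp_rate=15, wbc=9_000), 0, False),
            (SIRSProfile(), 0, False),  # all missing
            # mechanical ventilation satisfies the respiratory criterion
            (SIRSProfile(on_mech_vent=True, paco2=40.0), 1, False),
            (SIRSProfile(paco2=31.9), 1, False),  # PaCO2 < 32
            # all four fire
            (SIRSProfile(38.5, 120, 30, 30.0, True, 13_000), 4, True),
            # boundary WBC values are normal (strict < 4000 / > 12000)
            (SIRSProfile(temperature=37.0, wbc=12_000), 0, False),
            (SIRSProfile(temperature=35.9, wbc=3_999), 2, True),
        ],
    )
    def test_two_of_four_rule(self, profile, expected_count, expected_met):
        met, count = assess_sirs(profile)
        assert count == expected_count
        assert met is expected_met


class TestOrganDysfunction:
    def test_vasopressor_alone_is_shock(self):
        prof = OrganDysfunctionProfile(vasopressor_use=True)
        assert assess_organ_dysfunction(prof) == {"cardiovascular"}

    def test_pf_ratio_boundary_inclusive(self):
        assert assess_organ_dysfunction(
            OrganDysfunctionProfile(pao2_fio2=300.0)
        ) == {"pulmonary"}
        assert assess_organ_dysfunction(
            OrganDysfunctionProfile(pao2_fio2=300.5)
        ) == set()

    def test_hypotension_requires_acidosis(self):
        prof = OrganDysfunctionProfile(sbp=85.0, ph=7.35, vasopressor_use=False)
        assert "cardiovascular" not in assess_organ_dysfunction(prof)
        prof2 = OrganDysfunctionProfile(sbp=85.0, ph=7.30)
        assert "cardiovascular" in assess_organ_dysfunction(prof2)

    @pytest.mark.parametrize(
        "kwargs, system",
        [
            ({"map": 70.0, "ph": 7.3}, "cardiovascular"),
            ({"gcs": 12}, "cns"),
            ({"platelets": 80_000.0}, "coagulation"),
            ({"creatinine": 2.0}, "renal"),
            ({"bilirubin": 2.0}, "hepatic"),
        ],
    )
    def test_inclusive_thresholds(self, kwargs, system):
        assert assess_organ_dysfunction(OrganDysfunctionProfile(**kwargs)) == {system}

    def test_missing_values_never_qualify(self):
        assert assess_organ_dysfunction(OrganDysfunctionProfile()) == set()


class TestHighRisk:
    def test_apache_25_qualifies(self):
        rec = make_record(severity_score=25)
        hr, basis = assess_high_risk(rec, set())
        assert hr and basis == ["APACHE2>=25"]

    def test_saps_54_qualifies(self):
        rec = make_record(severity_score_type="SAPS2", severity_score=54)
        hr, basis = assess_high_risk(rec, set())
        assert hr and basis == ["SAPS2>=54"]

    def test_two_dysfunctions_within_two_days(self):
        rec = make_record(severity_score=20)
        hr, basis = assess_high_risk(rec)
        assert hr and basis[0].startswith("multi-organ")

    def test_onsets_three_days_apart_do_not_qualify(self):
        od = OrganDysfunctionProfile(
            systems={
                "cardiovascular": OrganSystemEntry(True, D(2004, 6, 1)),
                "pulmonary": OrganSystemEntry(True, D(2004, 6, 4)),
            },
            vasopressor_use=True,
            pao2_fio2=250.0,
        )
        rec = make_record(severity_score=20, organ_dysfunction=od)
        hr, _ = assess_high_risk(rec)
        assert not hr

    def test_missing_onset_pair_does_not_qualify(self):
        od = OrganDysfunctionProfile(
            systems={
                "cardiovascular": OrganSystemEntry(True, None),
                "pulmonary": OrganSystemEntry(True, D(2004, 6, 1)),
            },
            vasopressor_use=True,
            pao2_fio2=250.0,
        )
        rec = make_record(severity_score=20, organ_dysfunction=od)
        assert not assess_high_risk(rec)[0]


class TestTemporal:
    def test_exactly_24_months_before_is_eligible(self):
        rec = make_record(enrollment_date=D(2001, 1, 1))
        assert temporal_eligibility(rec, COHORT) is True

    def test_25_months_before_is_ineligible(self):
        rec = make_record(enrollment_date=D(2000, 12, 1))
        assert temporal_eligibility(rec, COHORT) is False

    def test_after_availability_is_eligible(self):
        cohort = CohortInfo("c1", "ctr1", D(2003, 6, 1), D(2003, 1, 1), "APACHE2")
        rec = make_record(enrollment_date=D(2004, 1, 1))
        assert temporal_eligibility(rec, cohort) is True

    def test_hospital_availability_takes_precedence(self):
        # availability later than approval: the lookback anchors on it
        cohort = CohortInfo("c1", "ctr1", D(2004, 1, 1), D(2003, 1, 1), "APACHE2")
        rec = make_record(enrollment_date=D(2001, 6, 1))
        assert temporal_eligibility(rec, cohort) is False

    def test_no_reference_date_is_configuration_error(self):
        cohort = CohortInfo("c1", "ctr1", None, None, "APACHE2")
        with pytest.raises(ConfigurationError):
            temporal_eligibility(make_record(), cohort)

    def test_month_end_clamping(self):
        assert months_before(D(2004, 3, 31), 1) == D(2004, 2, 29)
        assert months_before(D(2003, 3, 31), 1) == D(2003, 2, 28)
        assert months_before(D(2003, 1, 15), 24) == D(2001, 1, 15)


class TestClassifyPopulation:
    def test_fully_qualifying_is_indicated(self):
        res = classify_population(make_record(), COHORT)
        assert res.population == POP_INDICATED
        assert res.reasons == []

    def test_minor_is_excluded_for_age(self):
        res = classify_population(make_record(age=17.0), COHORT)
        assert res.population == POP_EXCLUDED
        assert "age" in res.reasons

    def test_not_high_risk_is_non_indicated(self):
        od = OrganDysfunctionProfile(
            systems={"cardiovascular": OrganSystemEntry(True, D(2004, 6, 1))},
            vasopressor_use=True,
        )
        rec = make_record(severity_score=20, organ_dysfunction=od)
        res = classify_population(rec, COHORT)
        assert res.population == POP_NON_INDICATED
        assert res.severe_sepsis

    def test_low_platelets_excluded_from_both_populations(self):
        res = classify_population(make_record(platelets=25_000.0), COHORT)
        assert res.population == POP_EXCLUDED
        assert "platelets" in res.reasons

    def test_every_exclusion_lists_a_reason(self, small_study):
        from sepsispgx.screen import screen_cohort

        elig = screen_cohort(small_study.patients, small_study.cohorts)
        excluded = elig[elig["population"] == POP_EXCLUDED]
        assert (excluded["reasons"].str.len() > 0).all()


class TestImputation:
    def _records(self, n=20, center="ctr1", missing_vent=0):
        rows = []
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"{center}_P{i}",
                    "center_id": center,
                    "age": 60.0,
                    "severity_score": 26.0,
                    "od_cardiovascular_present": True,
                    "od_pulmonary_present": False,
                    "od_renal_present": False,
                    "od_coagulation_present": False,
                    "ventilated": "missing" if i < missing_vent else "yes",
                    "medical_surgical": "medical",
                    "infection_site": "lung",
                }
            )
        return pd.DataFrame(rows)

    def _elig(self, records):
        return pd.DataFrame(
            {"patient_id": records["patient_id"], "population": POP_INDICATED}
        )

    def test_identity_on_complete_data(self):
        rec = self._records()
        out, audit = impute_matching_variables(rec, self._elig(rec))
        assert audit.empty
        assert not out["match_ineligible"].any()
        assert (out["ventilated"] == rec["ventilated"]).all()

    def test_center_above_30pct_missing_not_imputed(self):
        rec = self._records(n=20, missing_vent=8)  # 40% missing
        out, audit = impute_matching_variables(rec, self._elig(rec))
        assert audit.empty
        # un-imputed missing values leave those patients unmatchable
        assert out["match_ineligible"].sum() == 8

    def test_center_below_30pct_missing_imputed_with_mode(self):
        rec = self._records(n=20, missing_vent=4)  # 20% missing
        out, audit = impute_matching_variables(rec, self._elig(rec))
        assert len(audit) == 4
        assert (out["ventilated"] == "yes").all()
        assert not out["match_ineligible"].any()
        assert set(audit["variable"]) == {"ventilated"}

    def test_three_missing_variables_excludes_patient(self):
        rec = self._records(n=20)
        rec.loc[0, "ventilated"] = "missing"
        rec.loc[0, "medical_surgical"] = "unknown"
        rec.loc[0, "infection_site"] = "unknown"
        out, _ = impute_matching_variables(rec, self._elig(rec))
        assert bool(out.loc[0, "match_ineligible"])
        assert not out.loc[1:, "match_ineligible"].any()

    def test_missing_severity_score_never_imputed(self):
        rec = self._records(n=20)
        rec.loc[0, "severity_score"] = np.nan
        out, audit = impute_matching_variables(rec, self._elig(rec))
        assert bool(out.loc[0, "match_ineligible"])
        assert "severity_score" not in set(audit["variable"])

    def test_imputation_is_center_wise(self):
        rec = pd.concat(
            [self._records(20, "ctr1", missing_vent=4),
             self._records(20, "ctr2", missing_vent=0)],
            ignore_index=True,
        )
        # ctr2 donors all "yes"; make ctr1 donors majority "no"
        rec.loc[(rec["center_id"] == "ctr1") & (rec["ventilated"] == "yes"),
                "ventilated"] = "no"
        rec.loc[rec["ventilated"] == "missing", "ventilated"] = "missing"
        out, audit = impute_matching_variables(rec, self._elig(rec))
        filled = out[(out["center_id"] == "ctr1")
                     & out["patient_id"].isin(audit["patient_id"])]
        assert (filled["ventilated"] == "no").all()
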