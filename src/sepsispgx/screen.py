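"""Eligibility screening and population labels.

The study's primary population (INDICATED) mirrors the regulatory
indication for drotrecogin alfa (activated): adults with severe sepsis
(suspected/proven infection + SIRS + at least one sepsis-induced organ
dysfunction) at high risk of death (APACHE II >= 25, SAPS II >= 54, or
two or more organ dysfunctions with onsets within 2 days of each
other), platelets >= 30,000/mm3, known treatment status, and enrollment
no earlier than 24 months before the drug became available.  Patients
with severe sepsis who fail only the high-risk criterion form the
non-INDICATED population; the two merged give the severe-sepsis
(SEVSEP) population.

Eligibility is a pure function of transfer-1 data: no outcome or
genotype value can reach these functions.  No missing value is ever
imputed to satisfy an eligibility criterion; imputation
(:func:`impute_matching_variables`) applies only to matching variables
after eligibility is decided.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import pandas as pd

from .cohort import (
    MATCHING_SYSTEMS,
    CohortInfo,
    OrganDysfunctionProfile,
    PatientRecord,
    SIRSProfile,
    cohort_info_from_row,
    record_from_row,
)
from .config import StudyConfig
from .errors import ConfigurationError

POP_INDICATED = "INDICATED"
POP_NON_INDICATED = "NON_INDICATED"
POP_EXCLUDED = "EXCLUDED"

#: Matching variables eligible for center-wise imputation.  Age and the
#: severity score are never imputed; a patient missing either is
#: unmatchable.
IMPUTABLE_VARIABLES = (
    [f"od_{s}_present" for s in MATCHING_SYSTEMS]
    + ["ventilated", "medical_surgical", "infection_site"]
)

CONTINUOUS_IMPUTABLE: tuple[str, ...] = ()  # all current matching vars are categorical


@dataclass
class EligibilityResult:
    patient_id: str
    sirs_met: bool
    sirs_count: int
    organ_dysfunctions_met: set[str]
    severe_sepsis: bool
    high_risk: bool
    high_risk_basis: list[str]
    platelets_ok: bool
    temporal_ok: bool
    population: str
    reasons: list[str] = field(default_factory=list)


def assess_sirs(profile: SIRSProfile) -> tuple[bool, int]:
    """2-of-4 SIRS rule.  A missing vital never satisfies its criterion.

    Criteria: (i) temperature < 36 or > 38 C; (ii) heart rate > 90/min;
    (iii) respiratory rate > 20/min, or PaCO2 < 32 mm Hg, or mechanical
    ventilation; (iv) WBC < 4,000 or > 12,000 /mm3.  Temperature and WBC
    bounds are strict, as defined.
    """
    count = 0
    t = profile.temperature
    if t is not None and (t < 36.0 or t > 38.0):
        count += 1
    if profile.heart_rate is not None and profile.heart_rate > 90:
        count += 1
    resp = (
        (profile.resp_rate is not None and profile.resp_rate > 20)
        or (profile.paco2 is not None and profile.paco2 < 32)
        or (profile.on_mech_vent is True)
    )
    if resp:
        count += 1
    w = profile.wbc
    if w is not None and (w < 4_000 or w > 12_000):
        count += 1
    return count >= 2, count


def assess_organ_dysfunction(profile: OrganDysfunctionProfile) -> set[str]:
    """Derive the set of clinically significant organ dysfunctions.

    Cardiovascular: (SBP <= 90 and pH <= 7.3) or (MAP <= 70 and
    pH <= 7.3) or vasopressor use (shock by itself).  Pulmonary:
    PaO2/FiO2 <= 300.  CNS: GCS <= 12.  Coagulation: platelets
    <= 80,000.  Renal: creatinine >= 2.0.  Hepatic: bilirubin >= 2.0.
    All comparisons inclusive; a missing supporting value never
    satisfies a clause.
    """
    out: set[str] = set()
    ph_low = profile.ph is not None and profile.ph <= 7.3
    cardio = (
        (profile.sbp is not None and profile.sbp <= 90 and ph_low)
        or (profile.map is not None and profile.map <= 70 and ph_low)
        or (profile.vasopressor_use is True)
    )
    if cardio:
        out.add("cardiovascular")
    if profile.pao2_fio2 is not None and profile.pao2_fio2 <= 300:
        out.add("pulmonary")
    if profile.gcs is not None and profile.gcs <= 12:
        out.add("cns")
    if profile.platelets is not None and profile.platelets <= 80_000:
        out.add("coagulation")
    if profile.creatinine is not None and profile.creatinine >= 2.0:
        out.add("renal")
    if profile.bilirubin is not None and profile.bilirubin >= 2.0:
        out.add("hepatic")
    return out


def assess_high_risk(
    record: PatientRecord,
    dysfunctions: Optional[set[str]] = None,
) -> tuple[bool, list[str]]:
    """High risk of death: APACHE II >= 25, or SAPS II >= 54, or two or
    more organ dysfunctions with onset dates within 2 calendar days of
    each other (inclusive; a pair with a missing onset never qualifies).
    """
    basis: list[str] = []
    score = record.severity_score
    if score is not None:
        if record.severity_score_type == "APACHE2" and score >= 25:
            basis.append("APACHE2>=25")
        if record.severity_score_type == "SAPS2" and score >= 54:
            basis.append("SAPS2>=54")
    if dysfunctions is None:
        dysfunctions = assess_organ_dysfunction(record.organ_dysfunction)
    onsets = []
    for sysname in sorted(dysfunctions):
        entry = record.organ_dysfunction.systems.get(sysname)
        if entry is not None and entry.onset_date is not None:
            onsets.append((sysname, entry.onset_date))
    for (a, da), (b, db) in combinations(onsets, 2):
        if abs((da - db).days) <= 2:
            basis.append(f"multi-organ:{a}+{b}")
            break
    return bool(basis), basis


def months_before(date: dt.date, months: int) -> dt.date:
    """Whole-month arithmetic: same day-of-month ``months`` earlier,
    clamped to the end of the target month."""
    total = date.year * 12 + (date.month - 1) - months
    year, month = divmod(total, 12)
    month += 1
    # clamp day to target month length
    if month == 12:
        nxt = dt.date(year + 1, 1, 1)
    else:
        nxt = dt.date(year, month + 1, 1)
    last_day = (nxt - dt.timedelta(days=1)).day
    return dt.date(year, month, min(date.day, last_day))


def temporal_eligibility(
    record: PatientRecord,
    cohort: CohortInfo,
    window_months: int = 24,
) -> bool:
    """Enrollment after drug availability (or approval), or within the
    lookback window before that date — boundary inclusive."""
    reference = cohort.reference_date
    if reference is None:
        raise ConfigurationError(
            f"cohort {cohort.cohort_id!r} has no availability or approval date"
        )
    return record.enrollment_date >= months_before(reference, window_months)


def classify_population(
    record: PatientRecord,
    cohort: CohortInfo,
    config: StudyConfig | None = None,
) -> EligibilityResult:
    """Apply the full eligibility cascade and assign the population label.

    INDICATED requires: age >= 18, severe sepsis, high risk of death,
    platelets >= 30,000/mm3, known treatment status, and the temporal
    rule.  NON_INDICATED requires the same minus high risk.  The labels
    are disjoint; SEVSEP is their union.
    """
    window = config.temporal_window_months if config else 24
    sirs_met, sirs_count = assess_sirs(record.sirs)
    dysfunctions = assess_organ_dysfunction(record.organ_dysfunction)
    severe_sepsis = record.infection_suspected and sirs_met and len(dysfunctions) > 0
    high_risk, basis = assess_high_risk(record, dysfunctions)
    platelets_ok = record.platelets is not None and record.platelets >= 30_000
    temporal_ok = temporal_eligibility(record, cohort, window)

    reasons: list[str] = []
    if record.age < 18:
        reasons.append("age")
    if not severe_sepsis:
        if not record.infection_suspected:
            reasons.append("no_infection")
        if not sirs_met:
            reasons.append("sirs")
        if not dysfunctions:
            reasons.append("no_organ_dysfunction")
    if not platelets_ok:
        reasons.append("platelets")
    if not record.daa_status_known:
        reasons.append("daa_status_unknown")
    if not temporal_ok:
        reasons.append("temporal")

    if not reasons and high_risk:
        population = POP_INDICATED
    elif not reasons:
        population = POP_NON_INDICATED
        reasons = ["not_high_risk"]
    else:
        population = POP_EXCLUDED
        if not high_risk:
            reasons.append("not_high_risk")

    return EligibilityResult(
        patient_id=record.patient_id,
        sirs_met=sirs_met,
        sirs_count=sirs_count,
        organ_dysfunctions_met=dysfunctions,
        severe_sepsis=severe_sepsis,
        high_risk=high_risk,
        high_risk_basis=basis,
        platelets_ok=platelets_ok,
        temporal_ok=temporal_ok,
        population=population,
        reasons=reasons,
    )


def screen_cohort(
    patients: pd.DataFrame,
    cohorts: pd.DataFrame,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Screen every patient; returns one row per patient with flags,
    reasons and the population label."""
    cohort_map = {
        row["cohort_id"]: cohort_info_from_row(row) for _, row in cohorts.iterrows()
    }
    rows = []
    for _, prow in patients.iterrows():
        rec = record_from_row(prow)
        if rec.cohort_id not in cohort_map:
            raise ConfigurationError(f"patient {rec.patient_id!r}: unknown cohort "
                                     f"{rec.cohort_id!r}")
        res = classify_population(rec, cohort_map[rec.cohort_id], config)
        rows.append(
            {
                "patient_id": res.patient_id,
                "population": res.population,
                "severe_sepsis": res.severe_sepsis,
                "sirs_met": res.sirs_met,
                "sirs_count": res.sirs_count,
                "n_organ_dysfunctions": len(res.organ_dysfunctions_met),
                "organ_dysfunctions": "|".join(sorted(res.organ_dysfunctions_met)),
                "high_risk": res.high_risk,
                "high_risk_basis": "|".join(res.high_risk_basis),
                "platelets_ok": res.platelets_ok,
                "temporal_ok": res.temporal_ok,
                "reasons": "|".join(res.reasons),
            }
        )
    return pd.DataFrame(rows)


def impute_matching_variables(
    records: pd.DataFrame,
    eligibility: pd.DataFrame,
    population: str = POP_INDICATED,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center-wise imputation of matching variables after eligibility.

    Within the stated population, a variable is imputed at a center only
    when the center's missingness for it is strictly below the
    configured cap (default 30%): continuous variables take the center
    median (lower median on even counts), categorical the center mode
    (alphabetically first on ties).  At most two matching variables may
    be imputed per patient; patients needing more, or missing age or
    their severity score (never imputable), are flagged
    ``match_ineligible``.

    Returns the records with imputed values filled plus
    ``match_ineligible`` / ``n_imputed`` columns, and an audit table
    with one row per imputed cell.
    """
    cfg = config or StudyConfig()
    out = records.copy()
    pop_ids = set(eligibility.loc[eligibility["population"] == population, "patient_id"])
    in_pop = out["patient_id"].isin(pop_ids)

    def _missing(col: pd.Series) -> pd.Series:
        return col.isna() | col.astype(object).isin(["missing", "unknown", None])

    audit_rows = []
    n_imputed = pd.Series(0, index=out.index)
    for center, idx in out.loc[in_pop].groupby("center_id").groups.items():
        sub = out.loc[idx]
        for var in IMPUTABLE_VARIABLES:
            miss = _missing(sub[var])
            if not miss.any():
                continue
            frac = miss.mean()
            if frac >= cfg.max_center_missing_fraction:
                continue  # too much missingness at this center: leave as is
            donors = sub.loc[~miss, var]
            if donors.empty:
                continue
            if var in CONTINUOUS_IMPUTABLE:
                vals = donors.sort_values()
                fill = vals.iloc[(len(vals) - 1) // 2]  # lower median
            else:
                counts = donors.value_counts()
                top = counts[counts == counts.max()].index
                fill = sorted(top, key=str)[0]
            fill_idx = sub.index[miss]
            out.loc[fill_idx, var] = fill
            n_imputed.loc[fill_idx] += 1
            for i in fill_idx:
                audit_rows.append(
                    {
                        "patient_id": out.at[i, "patient_id"],
                        "center_id": center,
                        "variable": var,
                        "imputed_value": fill,
                        "center_missing_fraction": round(float(frac), 4),
                    }
                )

    # post-imputation matchability
    still_missing = pd.Series(0, index=out.index)
    for var in IMPUTABLE_VARIABLES:
        still_missing += _missing(out[var]).astype(int)
    core_missing = out["age"].isna() | out["severity_score"].isna()
    out["n_imputed"] = n_imputed
    out["match_ineligible"] = (
        core_missing
        | (n_imputed > cfg.max_imputed_variables)
        | (still_missing > 0)
    )
    audit = pd.DataFrame(
        audit_rows,
        columns=["patient_id", "center_id", "variable", "imputed_value",
                 "center_missing_fraction"],
    )
    return out, audit
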