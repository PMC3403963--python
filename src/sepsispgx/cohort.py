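"""Patient/cohort data model and the two-phase blinded data transfer.

The study receives data in two transfers.  Transfer 1 carries everything
needed for eligibility screening and matching — demographics, severity
scores, SIRS vitals, organ-dysfunction flags with onset dates — and
deliberately nothing else.  Only after the matched sets are locked
(:func:`lock_matches`) may transfer 2, which carries outcomes and
genotypes, be joined (:func:`join_transfer2`).  Blinding is structural:
:class:`PatientRecord` has no outcome or genotype fields, and any such
column found in a transfer-1 file is dropped with a warning.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import BlindingError, IntegrityError, SchemaError

ORGAN_SYSTEMS = ("cardiovascular", "pulmonary", "cns", "coagulation", "renal", "hepatic")

#: Organ systems used as matching variables (Mahalanobis + propensity).
MATCHING_SYSTEMS = ("cardiovascular", "pulmonary", "renal", "coagulation")

SEX_LEVELS = ("female", "male", "unknown")
TREATED_LEVELS = ("treated", "control")
SCORE_TYPES = ("APACHE2", "SAPS2")
MEDSURG_LEVELS = ("medical", "surgical", "unknown")
YESNO_LEVELS = ("yes", "no", "missing")
INFECTION_SITES = ("lung", "abdomen", "urinary", "other", "unknown")

#: Published column dictionary for transfer 1 (CSV/TSV, UTF-8).
TRANSFER1_COLUMNS = (
    ["patient_id", "cohort_id", "center_id", "age", "sex", "enrollment_date",
     "treated", "severity_score_type", "severity_score", "medical_surgical",
     "ventilated", "infection_site", "infection_suspected", "platelets",
     "daa_status_known"]
    + ["sirs_temperature", "sirs_heart_rate", "sirs_resp_rate", "sirs_paco2",
       "sirs_on_mech_vent", "sirs_wbc"]
    + [f"od_{s}_present" for s in ORGAN_SYSTEMS]
    + [f"od_{s}_onset_date" for s in ORGAN_SYSTEMS]
    + ["sup_sbp", "sup_map", "sup_ph", "sup_vasopressor", "sup_pao2_fio2",
       "sup_gcs", "sup_creatinine", "sup_bilirubin"]
)

COHORT_COLUMNS = ["cohort_id", "center_id", "daa_available_date",
                  "country_approval_date", "severity_score_type"]

TRANSFER2_COLUMNS = ["patient_id", "vital_status_day28", "in_hospital_death",
                     "discharge_day", "death_day", "vent_free_days",
                     "icu_free_days", "hospital_free_days"]

#: Outcome/genotype column names that must never appear in transfer 1.
_BLINDED_PREFIXES = ("snp_", "geno", "rs")
_BLINDED_NAMES = frozenset(
    c for c in TRANSFER2_COLUMNS if c != "patient_id"
) | {"dead28", "dead", "mortality", "outcome", "irp_a", "irp_b"}


@dataclass
class SIRSProfile:
    """Vitals for the 2-of-4 SIRS criteria; any field may be missing."""

    temperature: Optional[float] = None
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    paco2: Optional[float] = None
    on_mech_vent: Optional[bool] = None
    wbc: Optional[float] = None


@dataclass
class OrganSystemEntry:
    present: Optional[bool] = None
    onset_date: Optional[dt.date] = None


@dataclass
class OrganDysfunctionProfile:
    """Per-system dysfunction flags with onset dates plus the raw
    supporting measurements the flags are derived from."""

    systems: dict[str, OrganSystemEntry] = field(
        default_factory=lambda: {s: OrganSystemEntry() for s in ORGAN_SYSTEMS}
    )
    sbp: Optional[float] = None
    map: Optional[float] = None
    ph: Optional[float] = None
    vasopressor_use: Optional[bool] = None
    pao2_fio2: Optional[float] = None
    gcs: Optional[int] = None
    platelets: Optional[float] = None
    creatinine: Optional[float] = None
    bilirubin: Optional[float] = None


@dataclass
class PatientRecord:
    """One subject's baseline state.  Carries no outcome or genotype."""

    patient_id: str
    cohort_id: str
    center_id: str
    age: float
    sex: str
    enrollment_date: dt.date
    treated: str
    severity_score_type: str
    severity_score: Optional[float]
    medical_surgical: str
    ventilated: str
    infection_site: str
    infection_suspected: bool
    platelets: Optional[float]
    daa_status_known: bool
    sirs: SIRSProfile = field(default_factory=SIRSProfile)
    organ_dysfunction: OrganDysfunctionProfile = field(default_factory=OrganDysfunctionProfile)

    @property
    def is_treated(self) -> bool:
        return self.treated == "treated"


@dataclass
class CohortInfo:
    cohort_id: str
    center_id: str
    daa_available_date: Optional[dt.date]
    country_approval_date: Optional[dt.date]
    severity_score_type: str

    @property
    def reference_date(self) -> Optional[dt.date]:
        """Temporal-eligibility anchor: in-hospital availability if known,
        otherwise the country approval date."""
        return self.daa_available_date or self.country_approval_date


@dataclass
class TransferReport:
    """Row-level diagnostics from reading a transfer file."""

    n_rows: int = 0
    n_parsed: int = 0
    dropped_columns: list[str] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def warning_count(self) -> int:
        return len(self.warnings)


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _parse_bool(value) -> Optional[bool]:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _parse_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    f = float(value)
    return None if np.isnan(f) else f


def sniff_delimiter(path: str | Path) -> str:
    """CSV vs TSV auto-detection on the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _is_blinded_column(name: str) -> bool:
    low = name.lower()
    return low in _BLINDED_NAMES or any(low.startswith(p) for p in _BLINDED_PREFIXES)


# ---------------------------------------------------------------------------
# transfer 1

def read_transfer1(
    path: str | Path,
    config: StudyConfig | None = None,
    cohorts_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TransferReport]:
    """Read the transfer-1 file (eligibility + matching data only).

    Any outcome or genotype column present in the file is dropped with a
    warning — transfer 1 must not expose them.  Rows failing validation
    are rejected individually and listed in the report.

    Returns
    -------
    (patients, cohorts, report)
        ``patients`` uses the transfer-1 column dictionary with dates as
        :class:`datetime.date`; ``cohorts`` is empty when no cohort file
        is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = TransferReport()

    df = pd.read_csv(path, sep=sniff_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in TRANSFER1_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"transfer-1 file missing mandatory columns: {missing}")

    blinded = [c for c in df.columns if _is_blinded_column(c)]
    for col in blinded:
        report.dropped_columns.append(col)
        report.warnings.append(
            f"blinded column {col!r} present in transfer-1 file; dropped"
        )
    df = df.drop(columns=blinded)

    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise IntegrityError(
            f"duplicate patient_id in transfer 1: {sorted(set(dup))}"
        )

    report.n_rows = len(df)
    rows: list[dict] = []
    for i, raw in enumerate(df.to_dict("records")):
        try:
            rows.append(_validate_t1_row(raw, config))
        except (ValueError, KeyError) as exc:
            report.rejected.append((i, str(exc)))
    report.n_parsed = len(rows)

    patients = pd.DataFrame(rows, columns=TRANSFER1_COLUMNS)
    if cohorts_path is not None:
        cohorts = read_cohorts(cohorts_path)
    else:
        cohorts = pd.DataFrame(columns=COHORT_COLUMNS)
    return patients, cohorts, report


def _validate_t1_row(raw: dict, config: StudyConfig | None) -> dict:
    out = dict(raw)
    if not raw["patient_id"]:
        raise ValueError("empty patient_id")
    out["age"] = _parse_float(raw["age"])
    if out["age"] is None or out["age"] < 0:
        raise ValueError(f"invalid age {raw['age']!r}")
    if raw["sex"] not in SEX_LEVELS:
        raise ValueError(f"invalid sex {raw['sex']!r}")
    if raw["treated"] not in TREATED_LEVELS:
        raise ValueError(f"invalid treated {raw['treated']!r}")
    if raw["severity_score_type"] not in SCORE_TYPES:
        raise ValueError(f"invalid severity_score_type {raw['severity_score_type']!r}")
    if raw["medical_surgical"] not in MEDSURG_LEVELS:
        raise ValueError(f"invalid medical_surgical {raw['medical_surgical']!r}")
    if raw["ventilated"] not in YESNO_LEVELS:
        raise ValueError(f"invalid ventilated {raw['ventilated']!r}")
    if raw["infection_site"] not in INFECTION_SITES:
        raise ValueError(f"invalid infection_site {raw['infection_site']!r}")
    out["enrollment_date"] = _parse_date(raw["enrollment_date"])
    if out["enrollment_date"] is None:
        raise ValueError("missing enrollment_date")
    sev = _parse_float(raw["severity_score"])
    if sev is not None and sev < 0:
        raise ValueError(f"negative severity_score {sev}")
    out["severity_score"] = sev
    out["platelets"] = _parse_float(raw["platelets"])
    out["infection_suspected"] = bool(_parse_bool(raw["infection_suspected"]))
    out["daa_status_known"] = bool(_parse_bool(raw["daa_status_known"]))
    for col in ("sirs_temperature", "sirs_heart_rate", "sirs_resp_rate",
                "sirs_paco2", "sirs_wbc", "sup_sbp", "sup_map", "sup_ph",
                "sup_pao2_fio2", "sup_gcs", "sup_creatinine", "sup_bilirubin"):
        out[col] = _parse_float(raw[col])
    for col in ("sirs_on_mech_vent", "sup_vasopressor"):
        out[col] = _parse_bool(raw[col])
    for s in ORGAN_SYSTEMS:
        out[f"od_{s}_present"] = _parse_bool(raw[f"od_{s}_present"])
        out[f"od_{s}_onset_date"] = _parse_date(raw[f"od_{s}_onset_date"])
    return out


def read_cohorts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=sniff_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns: {missing}")
    dup = df["cohort_id"][df["cohort_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate cohort_id: {sorted(set(dup))}")
    df = df[COHORT_COLUMNS].copy()
    for col in ("daa_available_date", "country_approval_date"):
        df[col] = df[col].map(_parse_date)
    for _, row in df.iterrows():
        if row["daa_available_date"] is None and row["country_approval_date"] is None:
            raise SchemaError(
                f"cohort {row['cohort_id']!r} has neither an availability "
                f"nor an approval date"
            )
        if row["severity_score_type"] not in SCORE_TYPES:
            raise SchemaError(
                f"cohort {row['cohort_id']!r}: invalid severity_score_type"
            )
    return df


def write_transfer1(patients: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    patients[TRANSFER1_COLUMNS].to_csv(path, sep=sep, index=False)


def write_cohorts(cohorts: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    cohorts[COHORT_COLUMNS].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# record <-> frame conversion

def record_from_row(row: dict | pd.Series) -> PatientRecord:
    """Build a :class:`PatientRecord` from one parsed transfer-1 row."""
    if isinstance(row, pd.Series):
        row = row.to_dict()
    sirs = SIRSProfile(
        temperature=row.get("sirs_temperature"),
        heart_rate=row.get("sirs_heart_rate"),
        resp_rate=row.get("sirs_resp_rate"),
        paco2=row.get("sirs_paco2"),
        on_mech_vent=row.get("sirs_on_mech_vent"),
        wbc=row.get("sirs_wbc"),
    )
    od = OrganDysfunctionProfile(
        systems={
            s: OrganSystemEntry(
                present=row.get(f"od_{s}_present"),
                onset_date=row.get(f"od_{s}_onset_date"),
            )
            for s in ORGAN_SYSTEMS
        },
        sbp=row.get("sup_sbp"),
        map=row.get("sup_map"),
        ph=row.get("sup_ph"),
        vasopressor_use=row.get("sup_vasopressor"),
        pao2_fio2=row.get("sup_pao2_fio2"),
        gcs=None if row.get("sup_gcs") is None else int(row["sup_gcs"]),
        platelets=row.get("platelets"),
        creatinine=row.get("sup_creatinine"),
        bilirubin=row.get("sup_bilirubin"),
    )
    return PatientRecord(
        patient_id=row["patient_id"],
        cohort_id=row["cohort_id"],
        center_id=row["center_id"],
        age=row["age"],
        sex=row["sex"],
        enrollment_date=row["enrollment_date"],
        treated=row["treated"],
        severity_score_type=row["severity_score_type"],
        severity_score=row["severity_score"],
        medical_surgical=row["medical_surgical"],
        ventilated=row["ventilated"],
        infection_site=row["infection_site"],
        infection_suspected=bool(row["infection_suspected"]),
        platelets=row["platelets"],
        daa_status_known=bool(row["daa_status_known"]),
        sirs=sirs,
        organ_dysfunction=od,
    )


def cohort_info_from_row(row: dict | pd.Series) -> CohortInfo:
    if isinstance(row, pd.Series):
        row = row.to_dict()
    return CohortInfo(
        cohort_id=row["cohort_id"],
        center_id=row["center_id"],
        daa_available_date=row.get("daa_available_date"),
        country_approval_date=row.get("country_approval_date"),
        severity_score_type=row["severity_score_type"],
    )


# ---------------------------------------------------------------------------
# matched-set lock and transfer 2

@dataclass(frozen=True)
class LockToken:
    """Opaque content-hash of matched-set membership.  Any change to the
    membership after lock invalidates the token."""

    digest: str

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"lock_token": self.digest}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "LockToken":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(digest=data["lock_token"])


def lock_matches(matches: Iterable) -> LockToken:
    """Derive the lock token from matched-set membership.

    The token is the SHA-256 of the sorted ``(treated_id, controls)``
    membership list, so it is invariant to set order but changes with
    any membership edit.
    """
    matches = list(matches)
    if not matches:
        raise IntegrityError("cannot lock an empty match list")
    seen_controls: dict[str, str] = {}
    seen_treated: set[str] = set()
    membership = []
    for m in matches:
        if m.treated_id in seen_treated:
            raise IntegrityError(f"treated patient {m.treated_id!r} appears in two sets")
        seen_treated.add(m.treated_id)
        controls = sorted(m.control_ids)
        if not 1 <= len(controls) <= 3:
            raise IntegrityError(
                f"set for treated {m.treated_id!r} has {len(controls)} controls"
            )
        for c in controls:
            if c in seen_controls:
                raise IntegrityError(
                    f"control {c!r} appears in two matched sets "
                    f"(treated {seen_controls[c]!r} and {m.treated_id!r})"
                )
            seen_controls[c] = m.treated_id
        membership.append([m.treated_id, controls])
    membership.sort()
    payload = json.dumps(membership, separators=(",", ":")).encode()
    return LockToken(hashlib.sha256(payload).hexdigest())


def read_transfer2(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=sniff_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in TRANSFER2_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"transfer-2 file missing columns: {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate patient_id in transfer 2: {sorted(set(dup))}")
    out = df[TRANSFER2_COLUMNS].copy()
    for col in ("discharge_day", "death_day", "vent_free_days",
                "icu_free_days", "hospital_free_days"):
        out[col] = df[col].map(_parse_float)
    out["in_hospital_death"] = df["in_hospital_death"].map(_parse_bool)
    bad = ~out["vital_status_day28"].isin(["dead", "alive"])
    if bad.any():
        raise SchemaError(
            f"invalid vital_status_day28 values: "
            f"{sorted(set(out.loc[bad, 'vital_status_day28']))}"
        )
    for col in ("vent_free_days", "icu_free_days", "hospital_free_days"):
        vals = out[col].dropna()
        if ((vals < 0) | (vals > 28)).any():
            raise SchemaError(f"{col} outside [0, 28]")
    return out


def write_transfer2(outcomes: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    outcomes[TRANSFER2_COLUMNS].to_csv(path, sep=sep, index=False)


def primary_endpoint(outcomes: pd.DataFrame, mode: str = "in_hospital_day28") -> pd.Series:
    """Binary primary endpoint per patient.

    ``in_hospital_day28``: death on or before day 28 and before hospital
    discharge (patients discharged alive before day 28 count as alive).
    ``day28_all_location``: death by day 28 regardless of location.
    """
    dead28 = (outcomes["vital_status_day28"] == "dead") & (
        outcomes["death_day"].isna() | (outcomes["death_day"] <= 28)
    )
    if mode == "day28_all_location":
        return dead28.astype(int)
    if mode == "in_hospital_day28":
        in_hosp = outcomes["in_hospital_death"].fillna(True).astype(bool)
        return (dead28 & in_hosp).astype(int)
    raise ValueError(f"unknown endpoint mode {mode!r}")


def join_transfer2(
    records: pd.DataFrame,
    matches: Iterable,
    token: LockToken,
    path: str | Path,
    genotypes: Optional[dict[str, dict[str, str]]] = None,
    endpoint_mode: str = "in_hospital_day28",
) -> tuple[pd.DataFrame, TransferReport]:
    """Join outcomes (and optionally genotypes) onto the locked matched sets.

    Refuses to run unless ``token`` matches the membership of ``matches``
    — the blinding contract is that outcome data only meet the matched
    sets after lock.

    Returns an analysis table with one row per matched patient:
    ``set_id, patient_id, treated (0/1), outcome (0/1)``, the transfer-2
    outcome fields, and (if provided) one column per SNP.
    """
    matches = list(matches)
    if token is None or lock_matches(matches).digest != token.digest:
        raise BlindingError(
            "lock token missing or stale: matched sets must be locked "
            "before outcome data are joined"
        )
    report = TransferReport()
    outcomes = read_transfer2(path)

    rows = []
    for m in matches:
        rows.append((m.set_id, m.treated_id, 1))
        for c in m.control_ids:
            rows.append((m.set_id, c, 0))
    table = pd.DataFrame(rows, columns=["set_id", "patient_id", "treated"])

    known = set(table["patient_id"])
    unknown = [p for p in outcomes["patient_id"] if p not in known]
    for p in unknown:
        report.warnings.append(f"transfer-2 row for unknown patient {p!r} ignored")
    outcomes = outcomes[outcomes["patient_id"].isin(known)]

    merged = table.merge(outcomes, on="patient_id", how="left")
    missing_mask = merged["vital_status_day28"].isna()
    merged["outcome_missing"] = missing_mask
    report.n_rows = len(merged)
    report.n_parsed = int((~missing_mask).sum())
    for p in merged.loc[missing_mask, "patient_id"]:
        report.warnings.append(f"matched patient {p!r} absent from transfer 2")

    present = ~missing_mask
    merged["outcome"] = np.nan
    merged.loc[present, "outcome"] = primary_endpoint(
        merged.loc[present], mode=endpoint_mode
    ).to_numpy()

    if genotypes is not None:
        snp_ids = sorted({s for calls in genotypes.values() for s in calls})
        for snp in snp_ids:
            merged[f"snp_{snp}"] = merged["patient_id"].map(
                lambda p, snp=snp: genotypes.get(p, {}).get(snp)
            )
    return merged, report
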