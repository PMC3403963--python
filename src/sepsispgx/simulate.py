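"""Synthetic multi-center severe-sepsis cohorts.

The generator emulates the structure the matched-cohort design assumes:
ten cohorts across eight centers; drug exposure in under 10% of
patients, confounded by age (younger patients more likely treated) and
severity (sicker patients more likely treated); composite biomarker
positivity near the observed prevalences (IRP A 33.7%, IRP B 26.1%);
and a logistic outcome model in which the treatment effect differs by
biomarker stratum (absolute risk reduction ``arr_pos`` in positives,
``arr_neg`` in negatives).  Organ-dysfunction comorbidity is clustered
through a Gaussian copula; SIRS vitals and organ-dysfunction supporting
values are drawn consistent with the derived flags so the generated
records replay cleanly through eligibility screening.

Treatment and outcome intercepts are calibrated by deterministic
root-finding (:func:`calibrate_intercepts`) so the marginal treated
fraction and stratum mortalities hit their targets under the covariate
distribution.  Everything is reproducible under a fixed seed: each
generation stage draws from its own seeded integer-keyed stream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import ORGAN_SYSTEMS, TRANSFER1_COLUMNS, TRANSFER2_COLUMNS
from .errors import InfeasibleError
from .genotype import IRPDefinition, default_irp_definitions

ODS_MARGINALS = {
    "cardiovascular": 0.70,
    "pulmonary": 0.75,
    "cns": 0.20,
    "coagulation": 0.20,
    "renal": 0.45,
    "hepatic": 0.15,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the design's stated conditions: ten cohorts over
    eight centers, treated prevalence 8% (the drug was used in under
    10% of indicated patients), younger-and-sicker confounding on the
    treatment logit, biomarker prevalences 33.7% / 26.1%, control
    mortality 35% (severe-sepsis mortality runs 30-60%) with treated
    mortality reduced by 15 points in biomarker-positive and 1.5 points
    in biomarker-negative patients.
    """

    n_per_cohort: int = 400
    n_cohorts: int = 10
    n_centers: int = 8
    treated_fraction: float = 0.08
    age_mean: float = 62.0
    age_sd: float = 15.0
    age_range: tuple[float, float] = (18.0, 90.0)
    apache_mean: float = 27.0
    apache_sd: float = 6.0
    apache_range: tuple[float, float] = (10.0, 45.0)
    saps_mean: float = 50.0
    saps_sd: float = 11.0
    saps_range: tuple[float, float] = (20.0, 85.0)
    n_saps_cohorts: int = 3
    age_slope: float = -0.4      # per age SD on the treatment logit (< 0)
    severity_slope: float = 0.5  # per severity SD on the treatment logit (> 0)
    od_marginals: dict = field(default_factory=lambda: dict(ODS_MARGINALS))
    od_correlation: float = 0.2
    infection_site_probs: dict = field(
        default_factory=lambda: {"lung": 0.45, "abdomen": 0.25,
                                 "urinary": 0.15, "other": 0.15}
    )
    female_fraction: float = 0.40
    irp_prevalence: dict = field(default_factory=lambda: {"A": 0.337, "B": 0.261})
    outcome_biomarker: str = "A"
    p0_pos: float = 0.35
    p0_neg: float = 0.35
    arr_pos: float = 0.15
    arr_neg: float = 0.015
    aim_n_snps: int = 93
    aim_n_populations: int = 3
    aim_divergence: float = 0.15  # Fst-like allele-frequency divergence
    ancestry_probs: tuple[float, ...] = (0.75, 0.15, 0.10)
    missing_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for irp, prev in self.irp_prevalence.items():
            if not 0 < prev < 1:
                raise InfeasibleError(f"IRP {irp} prevalence must lie in (0,1)")
        for name, p0, arr in (("pos", self.p0_pos, self.arr_pos),
                              ("neg", self.p0_neg, self.arr_neg)):
            if not 0 < p0 < 1:
                raise InfeasibleError(f"control mortality p0_{name} must lie in (0,1)")
            if not 0 < p0 - arr < 1:
                raise InfeasibleError(
                    f"treated mortality p0_{name} - arr_{name} = {p0 - arr} "
                    f"must lie in (0,1)"
                )
        if not 0 < self.treated_fraction < 1:
            raise InfeasibleError("treated_fraction must lie in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame          # transfer-1 schema
    cohorts: pd.DataFrame           # cohort dictionary
    outcomes: pd.DataFrame          # transfer-2 schema (the truth table)
    genotypes: dict                 # patient_id -> {snp_id: genotype}
    irp_truth: pd.DataFrame         # patient_id, irp_id, status


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def _truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


# ---------------------------------------------------------------------------
# intercept calibration

def calibrate_intercepts(config: SimulationConfig,
                         n_quad: int = 200_000) -> dict[str, float]:
    """Deterministic intercepts for the treatment and outcome logits.

    The treatment intercept is root-found (Brent) so the large-sample
    average of sigmoid(b0 + slopes . z) over the covariate distribution
    equals the target treated fraction; the fixed-seed covariate sample
    makes the calibration reproducible.  Outcome intercepts per
    biomarker stratum are logits of the target control mortalities, and
    the treatment and interaction coefficients follow from the treated
    mortalities ``p0 - arr``.
    """
    rng = np.random.default_rng([config.seed % (2**31), 901])
    z_age = rng.standard_normal(n_quad)
    z_sev = rng.standard_normal(n_quad)
    eta = config.age_slope * z_age + config.severity_slope * z_sev

    def frac(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - config.treated_fraction

    lo, hi = -20.0, 20.0
    if frac(lo) > 0 or frac(hi) < 0:
        raise InfeasibleError(
            f"treated fraction {config.treated_fraction} unattainable"
        )
    b0_treat = float(brentq(frac, lo, hi, xtol=1e-10))

    out = {"treatment": b0_treat}
    for name, p0, arr in (("pos", config.p0_pos, config.arr_pos),
                          ("neg", config.p0_neg, config.arr_neg)):
        out[f"outcome_{name}_control"] = float(logit(p0))
        out[f"outcome_{name}_treated"] = float(logit(p0 - arr))
    # saturated logistic parameterization of the 2x2 cell probabilities
    out["outcome_intercept"] = out["outcome_neg_control"]
    out["outcome_beta_treat"] = out["outcome_neg_treated"] - out["outcome_neg_control"]
    out["outcome_beta_irp"] = out["outcome_pos_control"] - out["outcome_neg_control"]
    out["outcome_beta_interaction"] = (
        (out["outcome_pos_treated"] - out["outcome_pos_control"])
        - out["outcome_beta_treat"]
    )
    return out


# ---------------------------------------------------------------------------
# genotypes

def solve_carrier_frequency(prevalence: float) -> tuple[float, float]:
    """Invert the composite two-SNP OR rule assuming the SNPs contribute
    symmetrically and independently: per-SNP responsive probability q
    from 1 - (1-q)^2 = prevalence, then allele frequency f from a
    carrier responsive set (1 - (1-f)^2 = q) under Hardy-Weinberg."""
    if not 0 < prevalence < 1:
        raise InfeasibleError(f"prevalence {prevalence} not attainable")
    q = 1.0 - np.sqrt(1.0 - prevalence)
    f = 1.0 - np.sqrt(1.0 - q)
    return float(q), float(f)


def generate_genotypes(
    config: SimulationConfig,
    patients: pd.DataFrame,
    definitions: Optional[dict[str, IRPDefinition]] = None,
) -> dict[str, dict[str, str]]:
    """Draw the 4 biomarker SNPs and the 93-SNP AIM panel per patient.

    Biomarker SNP allele frequencies are solved so the composite
    positivity rate equals the configured prevalence (carrier model,
    Hardy-Weinberg, SNPs independent).  AIM SNPs are drawn per latent
    ancestral population with Balding-Nichols diverged frequencies.
    """
    defs = definitions or default_irp_definitions()
    rng = _rng(config, 101)
    pids = patients["patient_id"].tolist()
    n = len(pids)
    genotypes: dict[str, dict[str, str]] = {p: {} for p in pids}

    for irp_id, definition in sorted(defs.items()):
        prev = config.irp_prevalence.get(irp_id)
        if prev is None:
            continue
        _, f = solve_carrier_frequency(prev)
        for snp in definition.snps:
            # minor allele = the one whose carriers are responsive
            (minor,) = {a for g in snp.responsive_genotypes for a in g
                        if all(a in g for g in snp.responsive_genotypes)} or {
                snp.alleles[0]
            }
            major = snp.alleles[0] if snp.alleles[1] == minor else snp.alleles[1]
            dosage = rng.binomial(2, f, size=n)
            for pid, d in zip(pids, dosage):
                g = {0: major + major, 1: major + minor, 2: minor + minor}[int(d)]
                genotypes[pid][snp.snp_id] = "".join(sorted(g))

    # AIM panel: latent ancestry with Balding-Nichols divergence
    probs = np.asarray(config.ancestry_probs[: config.aim_n_populations], dtype=float)
    probs = probs / probs.sum()
    ancestry = rng.choice(config.aim_n_populations, size=n, p=probs)
    fst = config.aim_divergence
    base = rng.uniform(0.1, 0.9, size=config.aim_n_snps)
    if fst > 0 and config.aim_n_populations > 1:
        a = base * (1 - fst) / fst
        b = (1 - base) * (1 - fst) / fst
        pop_freqs = rng.beta(a, b, size=(config.aim_n_populations, config.aim_n_snps))
    else:
        pop_freqs = np.tile(base, (config.aim_n_populations, 1))
    for j in range(config.aim_n_snps):
        snp_id = f"AIM{j + 1:03d}"
        fj = pop_freqs[ancestry, j]
        dosage = rng.binomial(2, fj)
        for pid, d in zip(pids, dosage):
            g = {0: "AA", 1: "AG", 2: "GG"}[int(d)]
            genotypes[pid][snp_id] = g
    generate_genotypes.last_ancestry = pd.Series(ancestry, index=pids)  # diagnostic
    return genotypes


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(config: SimulationConfig,
                    with_genotypes: bool = True) -> SyntheticCohort:
    """Generate a full synthetic study: transfer-1 patients, cohort
    dictionary, transfer-2 outcome truth, genotypes and IRP truth.

    ``with_genotypes=False`` skips the SNP panel and draws latent
    biomarker status directly by prevalence (cheaper when only the
    clinical pipeline is exercised); the outcome model is identical.
    """
    intercepts = calibrate_intercepts(config)
    n_total = config.n_per_cohort * config.n_cohorts
    rng_base = _rng(config, 1)
    rng_clin = _rng(config, 2)
    rng_out = _rng(config, 3)

    cohort_ids = [f"cohort{i + 1:02d}" for i in range(config.n_cohorts)]
    center_of = {
        c: f"center{(i % config.n_centers) + 1}" for i, c in enumerate(cohort_ids)
    }
    score_type_of = {
        c: ("SAPS2" if i < config.n_saps_cohorts else "APACHE2")
        for i, c in enumerate(cohort_ids)
    }
    approval = dt.date(2003, 1, 1)
    cohorts = pd.DataFrame(
        {
            "cohort_id": cohort_ids,
            "center_id": [center_of[c] for c in cohort_ids],
            "daa_available_date": [
                approval + dt.timedelta(days=int(d))
                for d in rng_base.integers(0, 365, size=config.n_cohorts)
            ],
            "country_approval_date": [approval] * config.n_cohorts,
            "severity_score_type": [score_type_of[c] for c in cohort_ids],
        }
    )

    cohort_col = np.repeat(cohort_ids, config.n_per_cohort)
    pids = [f"P{i + 1:05d}" for i in range(n_total)]

    age = _truncnorm(rng_base, config.age_mean, config.age_sd,
                     *config.age_range, n_total).round(1)
    is_saps = np.array([score_type_of[c] == "SAPS2" for c in cohort_col])
    sev = np.empty(n_total)
    sev[~is_saps] = _truncnorm(rng_base, config.apache_mean, config.apache_sd,
                               *config.apache_range, int((~is_saps).sum()))
    sev[is_saps] = _truncnorm(rng_base, config.saps_mean, config.saps_sd,
                              *config.saps_range, int(is_saps.sum()))
    sev = np.rint(sev)

    z_age = (age - config.age_mean) / config.age_sd
    z_sev = np.where(
        is_saps,
        (sev - config.saps_mean) / config.saps_sd,
        (sev - config.apache_mean) / config.apache_sd,
    )
    eta_t = (intercepts["treatment"] + config.age_slope * z_age
             + config.severity_slope * z_sev)
    treated = rng_base.random(n_total) < expit(eta_t)

    # organ dysfunction via Gaussian copula with common correlation
    systems = list(ORGAN_SYSTEMS)
    rho = config.od_correlation
    shared = rng_clin.standard_normal(n_total)
    od = {}
    for s in systems:
        zi = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng_clin.standard_normal(n_total)
        od[s] = zi < norm.ppf(config.od_marginals.get(s, 0.0))

    ref_dates = dict(zip(cohorts["cohort_id"], cohorts["daa_available_date"]))
    offset = rng_clin.integers(-28 * 30, 48 * 30, size=n_total)
    enrollment = np.array(
        [ref_dates[c] + dt.timedelta(days=int(d)) for c, d in zip(cohort_col, offset)]
    )

    # supporting values consistent with the dysfunction flags
    sup_vaso = od["cardiovascular"]
    sup_sbp = np.where(od["cardiovascular"],
                       rng_clin.uniform(60, 90, n_total),
                       rng_clin.uniform(95, 140, n_total)).round(0)
    sup_map = np.where(od["cardiovascular"],
                       rng_clin.uniform(45, 70, n_total),
                       rng_clin.uniform(75, 100, n_total)).round(0)
    sup_ph = np.where(od["cardiovascular"],
                      rng_clin.uniform(7.05, 7.30, n_total),
                      rng_clin.uniform(7.32, 7.45, n_total)).round(2)
    sup_pf = np.where(od["pulmonary"],
                      rng_clin.uniform(80, 300, n_total),
                      rng_clin.uniform(310, 480, n_total)).round(0)
    sup_gcs = np.where(od["cns"],
                       rng_clin.integers(3, 13, n_total),
                       rng_clin.integers(13, 16, n_total))
    platelets = np.where(
        od["coagulation"],
        rng_clin.uniform(22_000, 80_000, n_total),
        rng_clin.uniform(90_000, 350_000, n_total),
    ).round(0)
    sup_creat = np.where(od["renal"],
                         rng_clin.uniform(2.0, 6.0, n_total),
                         rng_clin.uniform(0.5, 1.9, n_total)).round(2)
    sup_bili = np.where(od["hepatic"],
                        rng_clin.uniform(2.0, 12.0, n_total),
                        rng_clin.uniform(0.2, 1.9, n_total)).round(2)

    onset = {}
    for s in systems:
        d = rng_clin.integers(0, 3, size=n_total)  # onsets cluster within 2 days
        onset[s] = np.array(
            [e + dt.timedelta(days=int(x)) for e, x in zip(enrollment, d)]
        )

    ventilated = od["pulmonary"] | (rng_clin.random(n_total) < 0.30)
    sirs_temp = np.where(rng_clin.random(n_total) < 0.85,
                         rng_clin.uniform(38.1, 40.5, n_total),
                         rng_clin.uniform(36.2, 38.0, n_total)).round(1)
    sirs_hr = np.where(rng_clin.random(n_total) < 0.85,
                       rng_clin.uniform(91, 150, n_total),
                       rng_clin.uniform(60, 90, n_total)).round(0)
    sirs_rr = np.where(rng_clin.random(n_total) < 0.80,
                       rng_clin.uniform(21, 40, n_total),
                       rng_clin.uniform(12, 20, n_total)).round(0)
    sirs_paco2 = rng_clin.uniform(25, 55, n_total).round(0)
    sirs_wbc = np.where(rng_clin.random(n_total) < 0.80,
                        rng_clin.uniform(12_100, 35_000, n_total),
                        rng_clin.uniform(4_500, 11_900, n_total)).round(0)

    site_names = list(config.infection_site_probs)
    site_p = np.array([config.infection_site_probs[s] for s in site_names])
    sites = rng_clin.choice(site_names, size=n_total, p=site_p / site_p.sum())

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "cohort_id": cohort_col,
            "center_id": [center_of[c] for c in cohort_col],
            "age": age,
            "sex": np.where(rng_clin.random(n_total) < config.female_fraction,
                            "female", "male"),
            "enrollment_date": enrollment,
            "treated": np.where(treated, "treated", "control"),
            "severity_score_type": np.where(is_saps, "SAPS2", "APACHE2"),
            "severity_score": sev,
            "medical_surgical": np.where(rng_clin.random(n_total) < 0.8,
                                         "medical", "surgical"),
            "ventilated": np.where(ventilated, "yes", "no"),
            "infection_site": sites,
            "infection_suspected": rng_clin.random(n_total) < 0.97,
            "platelets": platelets,
            "daa_status_known": rng_clin.random(n_total) < 0.98,
            "sirs_temperature": sirs_temp,
            "sirs_heart_rate": sirs_hr,
            "sirs_resp_rate": sirs_rr,
            "sirs_paco2": sirs_paco2,
            "sirs_on_mech_vent": ventilated,
            "sirs_wbc": sirs_wbc,
            "sup_sbp": sup_sbp,
            "sup_map": sup_map,
            "sup_ph": sup_ph,
            "sup_vasopressor": sup_vaso,
            "sup_pao2_fio2": sup_pf,
            "sup_gcs": sup_gcs,
            "sup_creatinine": sup_creat,
            "sup_bilirubin": sup_bili,
        }
    )
    for s in systems:
        patients[f"od_{s}_present"] = od[s]
        patients[f"od_{s}_onset_date"] = onset[s]
    patients = patients[TRANSFER1_COLUMNS]

    if with_genotypes:
        genotypes = generate_genotypes(config, patients)
        from .genotype import classify_all

        irp_truth = classify_all(genotypes)
        drive = irp_truth[irp_truth["irp_id"] == config.outcome_biomarker]
        pos = patients["patient_id"].map(
            drive.set_index("patient_id")["status"].eq("positive")
        ).to_numpy()
    else:
        genotypes = {}
        rng_g = _rng(config, 101)
        rows = []
        status_of = {}
        for irp_id in sorted(config.irp_prevalence):
            prev = config.irp_prevalence[irp_id]
            draw = rng_g.random(n_total) < prev
            status_of[irp_id] = draw
            rows += [
                {"patient_id": p, "irp_id": irp_id,
                 "status": "positive" if d else "negative"}
                for p, d in zip(pids, draw)
            ]
        irp_truth = pd.DataFrame(rows, columns=["patient_id", "irp_id", "status"])
        pos = status_of[config.outcome_biomarker]

    p_death = np.where(
        pos,
        np.where(treated, config.p0_pos - config.arr_pos, config.p0_pos),
        np.where(treated, config.p0_neg - config.arr_neg, config.p0_neg),
    )
    dead = rng_out.random(n_total) < p_death
    death_day = np.where(dead, rng_out.integers(1, 29, size=n_total), np.nan)
    discharge = np.minimum(
        5 + rng_out.geometric(0.12, size=n_total), 60
    ).astype(float)
    discharge_day = np.where(dead, np.nan, discharge)
    los28 = np.where(dead, 28, np.minimum(discharge, 28))
    free = np.clip(28 - los28, 0, 28)
    outcomes = pd.DataFrame(
        {
            "patient_id": pids,
            "vital_status_day28": np.where(dead, "dead", "alive"),
            "in_hospital_death": dead,
            "discharge_day": discharge_day,
            "death_day": death_day,
            "vent_free_days": np.where(dead, 0, free).astype(float),
            "icu_free_days": np.where(dead, 0, free).astype(float),
            "hospital_free_days": np.where(dead, 0, free).astype(float),
        }
    )[TRANSFER2_COLUMNS]

    patients = inject_missingness(patients, config.missing_rates, config.seed)
    return SyntheticCohort(patients, cohorts, outcomes, genotypes, irp_truth)


def inject_missingness(
    patients: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Optionally blank out matching variables at configured per-variable
    rates (to exercise the imputation rules)."""
    if not rates:
        return patients
    out = patients.copy()
    rng = np.random.default_rng([seed % (2**31), 77])
    for var, rate in sorted(rates.items()):
        mask = rng.random(len(out)) < rate
        if out[var].dtype == object:
            out.loc[mask, var] = "missing" if var == "ventilated" else None
        else:
            out.loc[mask, var] = np.nan
        if var.startswith("od_") and var.endswith("_present"):
            out.loc[mask, var] = None
    return out


def write_study_files(study: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write transfer-1/transfer-2 CSVs, the cohort dictionary and the
    genotype TSV; returns the path map."""
    from pathlib import Path

    from .cohort import write_cohorts, write_transfer1, write_transfer2
    from .genotype import write_genotype_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transfer1": str(out / "transfer1.csv"),
        "cohorts": str(out / "cohorts.csv"),
        "transfer2": str(out / "transfer2.csv"),
        "genotypes": str(out / "genotypes.tsv"),
    }
    write_transfer1(study.patients, paths["transfer1"])
    write_cohorts(study.cohorts, paths["cohorts"])
    write_transfer2(study.outcomes, paths["transfer2"])
    write_genotype_tsv(study.genotypes, paths["genotypes"])
    return paths
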