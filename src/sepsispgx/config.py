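"""Study-level configuration.

:class:`StudyConfig` gathers the design constants of the matched-cohort
pharmacogenomic study: the matching calipers (age 5 years, APACHE II
2 points, SAPS II 4 points, propensity 0.6 standard deviations), the
1-3 variable control ratio, the 24-month temporal windows, the
imputation limits and the Bonferroni-split significance levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PhysiologicalRanges:
    """Soft validation bounds for SIRS vitals (used for warnings only)."""

    temperature: tuple[float, float] = (25.0, 45.0)
    heart_rate: tuple[float, float] = (0.0, 300.0)
    resp_rate: tuple[float, float] = (0.0, 80.0)
    paco2: tuple[float, float] = (5.0, 200.0)
    wbc: tuple[float, float] = (0.0, 500_000.0)


@dataclass
class StudyConfig:
    """Design constants for screening, matching and analysis.

    Parameters
    ----------
    age_caliper_years
        Maximum age difference within a matched pair (years).
    apache_caliper_points, saps_caliper_points
        Severity-score calipers, applied according to the cohort's score
        type (a 4-point SAPS II caliper is calibrated to be comparable
        with the 2-point APACHE II caliper).
    propensity_caliper_sd
        Propensity caliper as a multiple of the sample SD of the fitted
        propensity scores over the match-eligible population.
    max_controls_per_treated
        Variable matching ratio upper bound (1 to 3 controls).
    temporal_window_months
        Both the enrollment-date caliper within a pair and the
        eligibility lookback before drug approval/availability.
    max_imputed_variables
        Per-patient cap on imputed matching variables.
    max_center_missing_fraction
        A variable is imputed at a center only when its missingness
        there is strictly below this fraction.
    per_test_alpha, family_alpha
        Bonferroni split across the two biomarker hypotheses.
    pca_components
        Number of ancestry principal components carried as covariates.
    """

    age_caliper_years: float = 5.0
    apache_caliper_points: float = 2.0
    saps_caliper_points: float = 4.0
    propensity_caliper_sd: float = 0.6
    propensity_caliper_scale: str = "probability"  # or "logit"
    max_controls_per_treated: int = 2
    temporal_window_months: int = 24
    max_imputed_variables: int = 2
    max_center_missing_fraction: float = 0.30
    per_test_alpha: float = 0.025
    family_alpha: float = 0.05
    pca_components: int = 3
    interaction_screen_alpha: float = 0.05
    exact_infection_site_match: bool = False
    endpoint: str = "in_hospital_day28"  # or "day28_all_location"
    seed: int = 0
    physiological_ranges: PhysiologicalRanges = field(default_factory=PhysiologicalRanges)

    def __post_init__(self) -> None:
        for name in (
            "age_caliper_years",
            "apache_caliper_points",
            "saps_caliper_points",
            "propensity_caliper_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_controls_per_treated not in (1, 2, 3):
            raise ValueError("max_controls_per_treated must be 1, 2 or 3")
        for name in ("per_test_alpha", "family_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.temporal_window_months <= 0:
            raise ValueError("temporal_window_months must be > 0")
        if self.propensity_caliper_scale not in ("probability", "logit"):
            raise ValueError("propensity_caliper_scale must be 'probability' or 'logit'")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "StudyConfig":
        data = dict(data)
        ranges = data.pop("physiological_ranges", None)
        cfg = cls(**data)
        if ranges is not None:
            cfg.physiological_ranges = PhysiologicalRanges(
                **{k: tuple(v) for k, v in ranges.items()}
            )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("study", data))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"study": self.to_dict()}, fh, sort_keys=False)


def severity_caliper(config: StudyConfig, score_type: str) -> float:
    """Severity caliper width for a cohort's score type."""
    if score_type == "APACHE2":
        return config.apache_caliper_points
    if score_type == "SAPS2":
        return config.saps_caliper_points
    raise ValueError(f"unknown severity score type {score_type!r}")
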