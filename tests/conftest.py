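"""Shared fixtures: seeded synthetic studies and a full matching run."""

from __future__ import annotations

import pytest

from sepsispgx.config import StudyConfig
from sepsispgx.matching import build_edges, optimal_match
from sepsispgx.propensity import fit_propensity
from sepsispgx.screen import POP_INDICATED, impute_matching_variables, screen_cohort
from sepsispgx.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_per_cohort=150, n_cohorts=4, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_cohort(small_config)


def run_matching_pipeline(study, study_config: StudyConfig | None = None):
    """Screen -> impute -> propensity -> edges -> optimal match."""
    cfg = study_config or StudyConfig()
    elig = screen_cohort(study.patients, study.cohorts, cfg)
    records, _ = impute_matching_variables(study.patients, elig, POP_INDICATED, cfg)
    ok = set(elig.loc[elig["population"] == POP_INDICATED, "patient_id"])
    matchable = records[
        records["patient_id"].isin(ok) & ~records["match_ineligible"]
    ].reset_index(drop=True)
    prop = fit_propensity(matchable, cfg)
    edges, _ = build_edges(matchable, prop.scores, prop.caliper_width, cfg)
    result = optimal_match(edges, cfg, matchable)
    return {
        "config": cfg,
        "eligibility": elig,
        "matchable": matchable,
        "propensity": prop,
        "edges": edges,
        "result": result,
    }


@pytest.fixture(scope="session")
def full_pipeline():
    """Default-size confounded study (n = 4,000, ~8% treated) run through
    the whole matching pipeline."""
    study = generate_cohort(SimulationConfig(seed=20))
    out = run_matching_pipeline(study)
    out["study"] = study
    return out
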