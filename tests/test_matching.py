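"""Mahalanobis distances, calipers, lexicographic optimal matching (with
exhaustive oracle), and balance diagnostics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sepsispgx.config import StudyConfig
from sepsispgx.matching import (
    FeasibleEdge,
    MatchedSet,
    balance_table,
    build_edges,
    exhaustive_match,
    mahalanobis_distance,
    matches_from_frame,
    matches_to_frame,
    matching_features,
    optimal_match,
    verify_matches,
)

D = dt.date


def two_patient_cohort(**overrides):
    """One treated + one control in the same cohort, identical except
    for the overridden fields (given as (treated_value, control_value))."""
    base = {
        "age": (60.0, 60.0),
        "severity_score": (27.0, 27.0),
        "enrollment_date": (D(2004, 1, 1), D(2004, 6, 1)),
    }
    base.update(overrides)
    rows = []
    for i, role in enumerate(["treated", "control"]):
        rows.append(
            {
                "patient_id": f"P{i}",
                "cohort_id": "c1",
                "center_id": "ctr1",
                "treated": role,
                "severity_score_type": "APACHE2",
                "od_cardiovascular_present": True,
                "od_pulmonary_present": True,
                "od_renal_present": False,
                "od_coagulation_present": False,
                "ventilated": "yes",
                "medical_surgical": "medical",
                "infection_site": "lung",
                **{k: v[i] for k, v in base.items()},
            }
        )
    return pd.DataFrame(rows)


def _edges_for(records, score_gap=0.0, width=0.05):
    scores = pd.Series(
        [0.10, 0.10 + score_gap], index=records["patient_id"].to_numpy()
    )
    edges, _ = build_edges(records, scores, width, StudyConfig())
    return edges


class TestMahalanobis:
    def test_zero_iff_identical(self):
        x = np.array([1.0, 2.0, 3.0])
        assert mahalanobis_distance(x, x, np.eye(3)) == 0.0

    def test_identity_covariance_unit_difference(self):
        x = np.zeros(3)
        y = np.array([0.0, 1.0, 0.0])
        assert mahalanobis_distance(x, y, np.eye(3)) == pytest.approx(1.0)

    def test_diagonal_covariance_scales(self):
        cov = np.diag([1.0, 4.0])
        cov_inv = np.linalg.inv(cov)
        assert mahalanobis_distance(
            np.array([0.0, 0.0]), np.array([0.0, 2.0]), cov_inv
        ) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5))
        cov_inv = np.linalg.inv(A @ A.T + 5 * np.eye(5))
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert mahalanobis_distance(x, y, cov_inv) == pytest.approx(
            mahalanobis_distance(y, x, cov_inv)
        )


class TestCalipers:
    def test_age_gap_six_years_blocks_edge(self):
        assert _edges_for(two_patient_cohort(age=(60.0, 66.0))) == []

    def test_age_gap_five_years_allows_edge(self):
        assert len(_edges_for(two_patient_cohort(age=(60.0, 65.0)))) == 1

    def test_apache_two_points_inclusive(self):
        assert len(_edges_for(two_patient_cohort(severity_score=(27.0, 29.0)))) == 1
        assert _edges_for(two_patient_cohort(severity_score=(27.0, 30.0))) == []

    def test_saps_four_point_caliper(self):
        rec = two_patient_cohort(severity_score=(50.0, 54.0))
        rec["severity_score_type"] = "SAPS2"
        assert len(_edges_for(rec)) == 1
        rec = two_patient_cohort(severity_score=(50.0, 55.0))
        rec["severity_score_type"] = "SAPS2"
        assert _edges_for(rec) == []

    def test_propensity_gap_beyond_width_blocks_edge(self):
        # caliper width = 0.6 s_e; a 0.7 s_e gap must block the pair
        s_e = 0.05 / 0.6
        assert _edges_for(two_patient_cohort(), score_gap=0.7 * s_e, width=0.05) == []
        assert len(_edges_for(two_patient_cohort(), score_gap=0.4 * s_e, width=0.05)) == 1

    def test_enrollment_beyond_24_months_blocks_edge(self):
        rec = two_patient_cohort(
            enrollment_date=(D(2004, 1, 1), D(2006, 2, 1))
        )
        assert _edges_for(rec) == []
        rec = two_patient_cohort(
            enrollment_date=(D(2004, 1, 1), D(2006, 1, 1))
        )
        assert len(_edges_for(rec)) == 1

    def test_cross_cohort_pairs_never_form_edges(self):
        rec = two_patient_cohort()
        rec.loc[1, "cohort_id"] = "c2"
        assert _edges_for(rec) == []


def random_instance(rng, n_treated=None, n_controls=None):
    nt = n_treated or rng.integers(1, 6)
    nc = n_controls or rng.integers(1, 9)
    edges = []
    for t in range(nt):
        for c in range(nc):
            if rng.random() < 0.45:
                edges.append(
                    FeasibleEdge(f"T{t}", f"C{c}", float(rng.uniform(0, 10)), "c1")
                )
    return edges


class TestOptimalMatch:
    def test_single_treated_picks_nearest_at_ratio_one(self):
        edges = [FeasibleEdge("T1", "C1", 3.0, "c1"),
                 FeasibleEdge("T1", "C2", 1.0, "c1")]
        res = optimal_match(edges, StudyConfig(max_controls_per_treated=1))
        assert res.matches[0].control_ids == ["C2"]

    def test_coverage_beats_distance(self):
        # greedy would give T1 the cheap control and leave T2 unmatched
        edges = [
            FeasibleEdge("T1", "C1", 0.1, "c1"),
            FeasibleEdge("T2", "C1", 5.0, "c1"),
            FeasibleEdge("T1", "C2", 9.0, "c1"),
        ]
        res = optimal_match(edges, StudyConfig(max_controls_per_treated=1))
        assert res.n_matched_treated == 2

    def test_treated_without_edges_reported(self):
        rec = two_patient_cohort(age=(60.0, 70.0))
        edges = _edges_for(rec)
        res = optimal_match(edges, StudyConfig(), rec)
        assert res.matches == []
        assert list(res.unmatched["treated_id"]) == ["P0"]

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_instance(rng)
        res = optimal_match(edges, StudyConfig(max_controls_per_treated=3))
        cov, nc, dist = exhaustive_match(edges, max_ratio=3)
        assert res.n_matched_treated == cov
        assert res.n_controls == nc
        assert res.total_distance == pytest.approx(dist, abs=1e-9)

    def test_no_control_reuse_and_ratio_bounds(self, full_pipeline):
        seen = set()
        for m in full_pipeline["result"].matches:
            assert 1 <= len(m.control_ids) <= 3
            for c in m.control_ids:
                assert c not in seen
                seen.add(c)

    def test_determinism(self):
        rng = np.random.default_rng(99)
        edges = random_instance(rng, 5, 8)
        r1 = optimal_match(edges, StudyConfig())
        r2 = optimal_match(list(reversed(edges)), StudyConfig())
        assert [(m.treated_id, m.control_ids) for m in r1.matches] == [
            (m.treated_id, m.control_ids) for m in r2.matches
        ]

    def test_widening_caliper_never_reduces_matches(self, small_study):
        from conftest import run_matching_pipeline

        narrow = run_matching_pipeline(small_study, StudyConfig())
        wide_cfg = StudyConfig(age_caliper_years=10.0, apache_caliper_points=4.0,
                               saps_caliper_points=8.0)
        wide = run_matching_pipeline(small_study, wide_cfg)
        assert (wide["result"].n_matched_treated
                >= narrow["result"].n_matched_treated)


class TestBalance:
    def test_identical_populations_have_zero_std_diff(self):
        rec = pd.concat([two_patient_cohort()] * 10, ignore_index=True)
        rec["patient_id"] = [f"P{i}" for i in range(len(rec))]
        # vary ages pairwise so variances are nonzero but the treated and
        # control populations stay identical
        pair_ages = np.tile([55.0, 60.0, 65.0, 58.0, 62.0], 2)
        rec["age"] = np.repeat(pair_ages, 2)
        matches = [
            MatchedSet(f"s{i}", rec["patient_id"].iloc[2 * i],
                       [rec["patient_id"].iloc[2 * i + 1]], [0.0], "c1")
            for i in range(10)
        ]
        tbl = balance_table(matches, rec)
        assert (tbl["std_diff_before"].abs() < 1e-12).all()
        assert (tbl["std_diff_after"].abs() < 1e-12).all()

    def test_confounded_cohort_balance_improves(self, full_pipeline):
        tbl = balance_table(
            full_pipeline["result"].matches, full_pipeline["matchable"]
        ).set_index("variable")
        for var in ("age", "severity"):
            assert abs(tbl.loc[var, "std_diff_after"]) < abs(
                tbl.loc[var, "std_diff_before"]
            )

    def test_after_columns_report_matched_counts(self, full_pipeline):
        tbl = balance_table(
            full_pipeline["result"].matches, full_pipeline["matchable"]
        )
        res = full_pipeline["result"]
        assert (tbl["n_treated_after"] == res.n_matched_treated).all()
        assert (tbl["n_controls_after"] == res.n_controls).all()


class TestPostHocVerification:
    def test_every_matched_pair_passes_every_caliper(self, full_pipeline):
        checks = verify_matches(
            full_pipeline["result"].matches,
            full_pipeline["matchable"],
            full_pipeline["propensity"].scores,
            full_pipeline["propensity"].caliper_width,
            full_pipeline["config"],
        )
        assert checks["all_pass"].all()


def test_matches_frame_round_trip():
    matches = [
        MatchedSet("s1", "T1", ["C1", "C2"], [0.5, 0.7], "c1"),
        MatchedSet("s2", "T2", ["C3"], [0.2], "c2"),
    ]
    back = matches_from_frame(matches_to_frame(matches))
    assert [(m.set_id, m.treated_id, m.control_ids) for m in back] == [
        (m.set_id, m.treated_id, m.control_ids) for m in matches
    ]
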