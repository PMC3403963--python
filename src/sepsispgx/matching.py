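"""Optimal variable-ratio matching of treated patients to controls.

Each treated patient is matched to one to three controls from the same
cohort, subject to hard calipers (age within 5 years, APACHE II within
2 points or SAPS II within 4, propensity score within 0.6 SD,
enrollment within 24 months) with closeness measured by the Mahalanobis
distance over the matching variables.  Among caliper-feasible
matchings, the solver optimizes lexicographically: first the number of
treated patients matched at all, then the total number of matched
controls, then the total distance.  The lexicographic objective is
solved exactly as a single min-cost network flow with tiered integer
costs; an exhaustive-search oracle (:func:`exhaustive_match`) is
provided for verification on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MATCHING_SYSTEMS
from .config import StudyConfig, severity_caliper
from .screen import months_before

#: Fixed ordering of the Mahalanobis feature vector.
FEATURE_NAMES = (
    ["age", "severity"]
    + [f"od_{s}" for s in MATCHING_SYSTEMS]
    + ["ventilated", "medical"]
    + ["site_lung", "site_abdomen", "site_urinary", "site_other"]
)

#: Resolution at which distances are integerized for exact flow arithmetic.
COST_RESOLUTION = 1e-6


@dataclass
class FeasibleEdge:
    treated_id: str
    control_id: str
    distance: float
    cohort_id: str


@dataclass
class MatchedSet:
    set_id: str
    treated_id: str
    control_ids: list[str]
    distances: list[float]
    cohort_id: str

    @property
    def size(self) -> int:
        return 1 + len(self.control_ids)


@dataclass
class MatchResult:
    matches: list[MatchedSet]
    unmatched: pd.DataFrame  # treated_id, reason, nearest-miss diagnostics
    n_treated_total: int = 0

    @property
    def n_matched_treated(self) -> int:
        return len(self.matches)

    @property
    def n_controls(self) -> int:
        return sum(len(m.control_ids) for m in self.matches)

    @property
    def total_distance(self) -> float:
        return float(sum(sum(m.distances) for m in self.matches))


# ---------------------------------------------------------------------------
# features and distance

def matching_features(records: pd.DataFrame) -> pd.DataFrame:
    """Numeric matching-feature matrix in the fixed ordering (raw age and
    severity points; 0/1 indicators)."""
    f = pd.DataFrame(index=records.index)
    f["age"] = records["age"].astype(float)
    f["severity"] = records["severity_score"].astype(float)
    for s in MATCHING_SYSTEMS:
        f[f"od_{s}"] = (records[f"od_{s}_present"] == True).astype(float)  # noqa: E712
    f["ventilated"] = (records["ventilated"] == "yes").astype(float)
    f["medical"] = (records["medical_surgical"] == "medical").astype(float)
    for site in ("lung", "abdomen", "urinary", "other"):
        f[f"site_{site}"] = (records["infection_site"] == site).astype(float)
    if f.isna().any().any():
        bad = f.columns[f.isna().any()].tolist()
        raise ValueError(f"matching features contain missing values: {bad}")
    return f[FEATURE_NAMES]


def mahalanobis_distance(x: np.ndarray, y: np.ndarray, cov_inv: np.ndarray) -> float:
    """d = sqrt((x-y)' V^{-1} (x-y)) with V^{-1} precomputed."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    q = float(d @ cov_inv @ d)
    return float(np.sqrt(max(q, 0.0)))


def pooled_within_group_cov(
    features: pd.DataFrame,
    treated_mask: np.ndarray,
    ridge_eps: float = 1e-6,
    cond_threshold: float = 1e10,
) -> np.ndarray:
    """Pooled within-treatment-group covariance, ridge-regularized
    (add eps*tr(S)/p to the diagonal) when ill-conditioned."""
    X = features.to_numpy(dtype=float)
    p = X.shape[1]
    parts, dof = [], 0
    for mask in (treated_mask, ~treated_mask):
        sub = X[mask]
        if len(sub) >= 2:
            parts.append(np.cov(sub, rowvar=False) * (len(sub) - 1))
            dof += len(sub) - 1
    if dof == 0:
        # degenerate cohort (single treated and/or single control):
        # fall back to the overall covariance
        if len(X) < 2:
            raise ValueError("too few patients to estimate a covariance")
        parts = [np.cov(X, rowvar=False) * (len(X) - 1)]
        dof = len(X) - 1
    S = sum(parts) / dof
    S = np.atleast_2d(S)

    def _cond(M):
        w = np.linalg.eigvalsh(M)
        return np.inf if w.min() <= 0 else w.max() / w.min()

    if _cond(S) > cond_threshold:
        S = S + (ridge_eps * np.trace(S) / p) * np.eye(p)
    if _cond(S) > 1e14 or np.linalg.eigvalsh(S).min() <= 0:
        S = S + (1e-3 * max(np.trace(S), 1.0) / p) * np.eye(p)
        if np.linalg.eigvalsh(S).min() <= 0:
            raise np.linalg.LinAlgError(
                "matching covariance not positive definite after ridge"
            )
    return S


# ---------------------------------------------------------------------------
# caliper-feasible edges

CALIPER_NAMES = ("same_cohort", "enrollment", "age", "severity", "propensity")


def _caliper_checks(t_row, c_row, score_type: str, scores, width: float,
                    config: StudyConfig) -> dict[str, bool]:
    sev_cal = severity_caliper(config, score_type)
    lo = months_before(t_row["enrollment_date"], config.temporal_window_months)
    hi_ref = months_before(c_row["enrollment_date"], config.temporal_window_months)
    return {
        "same_cohort": t_row["cohort_id"] == c_row["cohort_id"],
        "enrollment": (c_row["enrollment_date"] >= lo)
        and (t_row["enrollment_date"] >= hi_ref),
        "age": abs(t_row["age"] - c_row["age"]) <= config.age_caliper_years,
        "severity": abs(t_row["severity_score"] - c_row["severity_score"]) <= sev_cal,
        "propensity": abs(scores[t_row["patient_id"]] - scores[c_row["patient_id"]])
        <= width + 1e-12,
    }


def build_edges(
    records: pd.DataFrame,
    propensity_scores: pd.Series,
    caliper_width: float,
    config: StudyConfig | None = None,
) -> tuple[list[FeasibleEdge], dict[str, np.ndarray]]:
    """Emit every treated-control pair satisfying all calipers, with its
    Mahalanobis distance.

    The distance covariance is the pooled within-treatment-group
    covariance estimated per cohort.  Returns the edge list and the
    per-cohort inverse covariance matrices (for diagnostics).
    """
    cfg = config or StudyConfig()
    edges: list[FeasibleEdge] = []
    cov_invs: dict[str, np.ndarray] = {}
    scores = propensity_scores.to_dict()

    for cohort_id, idx in records.groupby("cohort_id").groups.items():
        sub = records.loc[idx].reset_index(drop=True)
        feats = matching_features(sub)
        treated_mask = (sub["treated"] == "treated").to_numpy()
        if treated_mask.sum() == 0 or (~treated_mask).sum() == 0:
            continue
        S = pooled_within_group_cov(feats, treated_mask)
        S_inv = np.linalg.inv(S)
        cov_invs[cohort_id] = S_inv
        X = feats.to_numpy(dtype=float)
        score_type = sub["severity_score_type"].iloc[0]
        sev_cal = severity_caliper(cfg, score_type)

        t_idx = np.flatnonzero(treated_mask)
        c_idx = np.flatnonzero(~treated_mask)
        ages = sub["age"].to_numpy(dtype=float)
        sevs = sub["severity_score"].to_numpy(dtype=float)
        enr = sub["enrollment_date"].to_numpy()
        pscore = np.array([scores[p] for p in sub["patient_id"]])
        pids = sub["patient_id"].to_numpy()

        for ti in t_idx:
            lo = months_before(enr[ti], cfg.temporal_window_months)
            ok = (
                (np.abs(ages[c_idx] - ages[ti]) <= cfg.age_caliper_years)
                & (np.abs(sevs[c_idx] - sevs[ti]) <= sev_cal)
                & (np.abs(pscore[c_idx] - pscore[ti]) <= caliper_width + 1e-12)
            )
            for ci, feasible in zip(c_idx, ok):
                if not feasible:
                    continue
                # enrollment within 24 whole months in either direction
                if enr[ci] < lo:
                    continue
                if enr[ti] < months_before(enr[ci], cfg.temporal_window_months):
                    continue
                d = mahalanobis_distance(X[ti], X[ci], S_inv)
                edges.append(FeasibleEdge(pids[ti], pids[ci], d, cohort_id))
    return edges, cov_invs


# ---------------------------------------------------------------------------
# optimal matching by staged min-cost flow

def _lex_costs(edges: list[FeasibleEdge]) -> dict[tuple[str, str], int]:
    """Integerized edge costs with canonical tie-breaking: distances are
    ranked at 1e-6 resolution, ties broken by (treated_id, control_id)."""
    order = sorted(edges, key=lambda e: (round(e.distance / COST_RESOLUTION),
                                         e.treated_id, e.control_id))
    m = len(order)
    return {
        (e.treated_id, e.control_id): int(round(e.distance / COST_RESOLUTION)) * (m + 1) + r
        for r, e in enumerate(order)
    }


def optimal_match(
    edges: list[FeasibleEdge],
    config: StudyConfig | None = None,
    records: pd.DataFrame | None = None,
) -> MatchResult:
    """Solve the lexicographic matching problem exactly.

    Objective (in priority order): (1) maximize the number of treated
    patients with at least one control; (2) maximize the total number of
    matched controls, at most ``max_controls_per_treated`` per treated
    and each control used once; (3) minimize total Mahalanobis distance.
    The three tiers are folded into one min-cost flow by separating the
    integer cost scales.
    """
    cfg = config or StudyConfig()
    max_ratio = cfg.max_controls_per_treated
    treated_ids = sorted({e.treated_id for e in edges})
    cohort_of = {e.treated_id: e.cohort_id for e in edges}

    result_sets: list[MatchedSet] = []
    unmatched_rows: list[dict] = []

    if edges:
        costs = _lex_costs(edges)
        dist_of = {(e.treated_id, e.control_id): e.distance for e in edges}
        total_cost = sum(costs.values()) + 1
        B2 = total_cost                       # one extra control beats any distance
        B1 = (max_ratio * len(treated_ids) + 1) * B2 + total_cost  # coverage beats all

        G = nx.DiGraph()
        F = max_ratio * len(treated_ids)
        G.add_node("S", demand=-F)
        G.add_node("T", demand=F)
        G.add_edge("S", "T", capacity=F, weight=0)
        for t in treated_ids:
            G.add_edge("S", ("first", t), capacity=1, weight=-B1)
            G.add_edge(("first", t), ("t", t), capacity=1, weight=0)
            if max_ratio > 1:
                G.add_edge("S", ("extra", t), capacity=max_ratio - 1, weight=-B2)
                G.add_edge(("extra", t), ("t", t), capacity=max_ratio - 1, weight=0)
        controls = sorted({e.control_id for e in edges})
        for c in controls:
            G.add_edge(("c", c), "T", capacity=1, weight=0)
        for (t, c), w in sorted(costs.items()):
            G.add_edge(("t", t), ("c", c), capacity=1, weight=w)

        flow = nx.min_cost_flow(G)

        for t in treated_ids:
            chosen = [
                c for (kind, c), f in flow.get(("t", t), {}).items() if f > 0
            ]
            if chosen:
                chosen.sort()
                result_sets.append(
                    MatchedSet(
                        set_id=f"set_{t}",
                        treated_id=t,
                        control_ids=chosen,
                        distances=[dist_of[(t, c)] for c in chosen],
                        cohort_id=cohort_of[t],
                    )
                )
            else:
                unmatched_rows.append(
                    {"treated_id": t, "reason": "feasible controls taken by other sets"}
                )

    n_total = len(treated_ids)
    if records is not None:
        all_treated = records.loc[records["treated"] == "treated", "patient_id"]
        n_total = len(all_treated)
        edgeless = set(all_treated) - set(treated_ids)
        for t in sorted(edgeless):
            unmatched_rows.append({"treated_id": t, "reason": "no caliper-feasible control"})

    unmatched = pd.DataFrame(unmatched_rows, columns=["treated_id", "reason"])
    return MatchResult(matches=result_sets, unmatched=unmatched,
                       n_treated_total=n_total)


def nearest_miss_report(
    records: pd.DataFrame,
    unmatched: pd.DataFrame,
    propensity_scores: pd.Series,
    caliper_width: float,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """For each unmatched treated patient, the control failing the fewest
    calipers and the list of calipers it failed."""
    cfg = config or StudyConfig()
    scores = propensity_scores
    recs = records.set_index("patient_id", drop=False)
    rows = []
    for t in unmatched["treated_id"]:
        t_row = recs.loc[t]
        best = None
        for _, c_row in recs[(recs["treated"] == "control")
                             & (recs["cohort_id"] == t_row["cohort_id"])].iterrows():
            checks = _caliper_checks(
                t_row, c_row, t_row["severity_score_type"], scores, caliper_width, cfg
            )
            failed = [k for k, ok in checks.items() if not ok]
            if best is None or len(failed) < len(best[1]):
                best = (c_row["patient_id"], failed)
        rows.append(
            {
                "treated_id": t,
                "nearest_control": best[0] if best else None,
                "failed_calipers": "|".join(best[1]) if best else "no_controls_in_cohort",
            }
        )
    return pd.DataFrame(rows, columns=["treated_id", "nearest_control", "failed_calipers"])


# ---------------------------------------------------------------------------
# exhaustive oracle (small instances)

def exhaustive_match(
    edges: list[FeasibleEdge],
    max_ratio: int = 3,
) -> tuple[int, int, float]:
    """Brute-force lexicographic optimum ``(coverage, n_controls,
    total_distance)`` by dynamic programming over control subsets.

    Independent of the flow solver; intended for instances with at most
    ~6 treated and ~10 controls.
    """
    treated = sorted({e.treated_id for e in edges})
    controls = sorted({e.control_id for e in edges})
    cidx = {c: i for i, c in enumerate(controls)}
    adj: dict[str, list[tuple[int, float]]] = {t: [] for t in treated}
    for e in edges:
        adj[e.treated_id].append((cidx[e.control_id], e.distance))

    @lru_cache(maxsize=None)
    def best(i: int, used: int) -> tuple[int, int, float]:
        if i == len(treated):
            return (0, 0, 0.0)
        t = treated[i]
        avail = [(c, d) for c, d in adj[t] if not used >> c & 1]
        # option: leave t unmatched
        opt = best(i + 1, used)
        for k in range(1, min(max_ratio, len(avail)) + 1):
            for combo in combinations(avail, k):
                mask = used
                dist = 0.0
                for c, d in combo:
                    mask |= 1 << c
                    dist += d
                cov, nc, td = best(i + 1, mask)
                cand = (cov + 1, nc + k, td + dist)
                if (cand[0], cand[1], -cand[2]) > (opt[0], opt[1], -opt[2]):
                    opt = cand
        return opt

    out = best(0, 0)
    best.cache_clear()
    return out


def verify_matches(
    matches: list[MatchedSet],
    records: pd.DataFrame,
    propensity_scores: pd.Series,
    caliper_width: float,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Independent post-hoc re-check of every caliper for every matched
    pair; returns one row per pair with pass/fail per caliper."""
    cfg = config or StudyConfig()
    recs = records.set_index("patient_id", drop=False)
    rows = []
    for m in matches:
        t_row = recs.loc[m.treated_id]
        for c in m.control_ids:
            c_row = recs.loc[c]
            checks = _caliper_checks(
                t_row, c_row, t_row["severity_score_type"],
                propensity_scores, caliper_width, cfg,
            )
            rows.append({"set_id": m.set_id, "treated_id": m.treated_id,
                         "control_id": c, **checks,
                         "all_pass": all(checks.values())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# balance diagnostics

def _std_diff(mt, vt, mc, vc) -> float:
    denom = np.sqrt((vt + vc) / 2.0)
    return 0.0 if denom == 0 else float((mt - mc) / denom)


def balance_table(
    matches: list[MatchedSet],
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Before/after covariate balance for the matching variables.

    'Before' compares all treated with all controls; 'after' compares
    matched treated with matched controls weighted 1/m_s within each
    set (so every matched set contributes equally regardless of its
    control count).  Continuous variables get Welch t-tests,
    indicators chi-square tests (on effective counts in the weighted
    column).
    """
    feats = matching_features(records)
    feats = feats.set_index(records["patient_id"])
    treated_ids = records.loc[records["treated"] == "treated", "patient_id"]
    control_ids = records.loc[records["treated"] == "control", "patient_id"]

    m_treated = [m.treated_id for m in matches]
    m_controls, weights = [], []
    for m in matches:
        for c in m.control_ids:
            m_controls.append(c)
            weights.append(1.0 / len(m.control_ids))
    weights = np.asarray(weights, dtype=float)

    rows = []
    for var in FEATURE_NAMES:
        is_binary = set(np.unique(feats[var])) <= {0.0, 1.0}
        xt_b = feats.loc[treated_ids, var].to_numpy()
        xc_b = feats.loc[control_ids, var].to_numpy()
        xt_a = feats.loc[m_treated, var].to_numpy()
        xc_a = feats.loc[m_controls, var].to_numpy()

        mt_b, vt_b = xt_b.mean(), xt_b.var(ddof=1)
        mc_b, vc_b = xc_b.mean(), xc_b.var(ddof=1)
        mt_a, vt_a = xt_a.mean(), (xt_a.var(ddof=1) if len(xt_a) > 1 else 0.0)
        wsum = weights.sum()
        mc_a = float(np.average(xc_a, weights=weights))
        vc_a = float(np.average((xc_a - mc_a) ** 2, weights=weights))
        n_eff = float(wsum**2 / np.sum(weights**2)) if len(weights) else 0.0

        if is_binary:
            p_b = _prop_test(xt_b.sum(), len(xt_b), xc_b.sum(), len(xc_b))
            p_a = _prop_test(xt_a.sum(), len(xt_a), mc_a * n_eff, n_eff)
        else:
            p_b = float(stats.ttest_ind(xt_b, xc_b, equal_var=False).pvalue)
            p_a = _welch_p(mt_a, vt_a, len(xt_a), mc_a, vc_a, n_eff)

        rows.append(
            {
                "variable": var,
                "treated_mean_before": mt_b, "control_mean_before": mc_b,
                "std_diff_before": _std_diff(mt_b, vt_b, mc_b, vc_b),
                "p_before": p_b,
                "treated_mean_after": mt_a, "control_mean_after": mc_a,
                "std_diff_after": _std_diff(mt_a, vt_a, mc_a, vc_a),
                "p_after": p_a,
                "n_treated_after": len(xt_a), "n_controls_after": len(xc_a),
            }
        )
    return pd.DataFrame(rows)


def _prop_test(k1, n1, k2, n2) -> float:
    if min(n1, n2) == 0:
        return float("nan")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False).pvalue)


def _welch_p(m1, v1, n1, m2, v2, n2) -> float:
    if n1 < 2 or n2 < 2 or (v1 == 0 and v2 == 0):
        return float("nan")
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return float("nan")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / max(n2 - 1, 1e-9))
    return float(2 * stats.t.sf(abs(t), df))


def matches_to_frame(matches: list[MatchedSet]) -> pd.DataFrame:
    """Long-format matches table (set_id, role, patient_id, distance)."""
    rows = []
    for m in matches:
        rows.append({"set_id": m.set_id, "role": "treated",
                     "patient_id": m.treated_id, "distance": 0.0,
                     "cohort_id": m.cohort_id})
        for c, d in zip(m.control_ids, m.distances):
            rows.append({"set_id": m.set_id, "role": "control",
                         "patient_id": c, "distance": d, "cohort_id": m.cohort_id})
    return pd.DataFrame(rows, columns=["set_id", "role", "patient_id",
                                       "distance", "cohort_id"])


def matches_from_frame(frame: pd.DataFrame) -> list[MatchedSet]:
    out = []
    for set_id, grp in frame.groupby("set_id", sort=True):
        t = grp[grp["role"] == "treated"]
        c = grp[grp["role"] == "control"]
        out.append(
            MatchedSet(
                set_id=str(set_id),
                treated_id=t["patient_id"].iloc[0],
                control_ids=c["patient_id"].tolist(),
                distances=c["distance"].astype(float).tolist(),
                cohort_id=grp["cohort_id"].iloc[0],
            )
        )
    return out
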