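"""Primary matched-set analysis.

The primary endpoint (in-hospital mortality through day 28) is modeled
by conditional logistic regression, conditioning on the matched sets:
for a set s with d_s deaths among its n_s members, the likelihood
contribution is

    exp(sum_{i in deaths} x_i'b) / sum_{|C| = d_s} exp(sum_{i in C} x_i'b)

with the denominator enumerated exactly over all subsets of size d_s
(at most C(4,2) = 6 terms for 1:3 sets).  Sets with zero or n_s deaths
contribute nothing and are counted as dropped.  The covariates of the
primary model are treatment, biomarker status, their interaction, and
the ancestry principal components; each of the two biomarker hypotheses
is tested two-sided at alpha = 2.5% for a Bonferroni family level of 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import EstimationError

SetData = tuple[np.ndarray, np.ndarray]  # (X: n_s x p, y: n_s 0/1)


@dataclass
class AnalysisSpec:
    per_test_alpha: float = 0.025
    family_alpha: float = 0.05
    n_pcs: int = 3
    endpoint: str = "in_hospital_day28"

    def __post_init__(self):
        if not (0 < self.per_test_alpha < 1 and 0 < self.family_alpha < 1):
            raise ValueError("alpha levels must lie in (0,1)")


@dataclass
class ConditionalLogisticFit:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    estimable: bool
    n_sets: int
    n_informative: int
    n_dropped: int
    message: str = ""

    def se(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sqrt(self.cov[j, j]))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


# ---------------------------------------------------------------------------
# exact conditional likelihood

def _informative(sets: Sequence[SetData]) -> tuple[list[SetData], int]:
    keep, dropped = [], 0
    for X, y in sets:
        d = int(np.sum(y))
        if 0 < d < len(y):
            keep.append((np.asarray(X, dtype=float), np.asarray(y, dtype=float)))
        else:
            dropped += 1
    return keep, dropped


def _group(sets: Sequence[SetData]):
    """Group informative sets by (n_s, d_s) for vectorized evaluation."""
    groups: dict[tuple[int, int], list[SetData]] = {}
    for X, y in sets:
        groups.setdefault((len(y), int(np.sum(y))), []).append((X, y))
    out = []
    for (n, d), members in sorted(groups.items()):
        Xg = np.stack([X for X, _ in members])        # (m, n, p)
        yg = np.stack([y for _, y in members])        # (m, n)
        combs = np.array(list(combinations(range(n), d)))  # (n_sub, d)
        S = Xg[:, combs, :].sum(axis=2)               # (m, n_sub, p)
        s_obs = np.einsum("mn,mnp->mp", yg, Xg)       # (m, p)
        out.append((S, s_obs))
    return out


def _loglik_grouped(beta: np.ndarray, groups) -> tuple[float, np.ndarray, np.ndarray]:
    p = beta.shape[0]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for S, s_obs in groups:
        eta = S @ beta                                # (m, n_sub)
        lse = logsumexp(eta, axis=1)                  # (m,)
        ll += float(np.sum(np.sum(s_obs * beta, axis=1) - lse))
        w = np.exp(eta - lse[:, None])                # subset probabilities
        ES = np.einsum("ms,msp->mp", w, S)            # E[S] per set
        grad += np.sum(s_obs - ES, axis=0)
        ESS = np.einsum("ms,msp,msq->pq", w, S, S)    # sum_m E[SS']
        hess -= ESS - np.einsum("mp,mq->pq", ES, ES)
    return ll, grad, hess


def conditional_loglik(
    beta: np.ndarray, sets: Sequence[SetData]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact conditional log-likelihood with analytic gradient and
    Hessian, enumerating the within-set subset distribution.

    Concordant sets (all died or all survived) contribute zero.
    """
    beta = np.asarray(beta, dtype=float)
    informative, _ = _informative(sets)
    return _loglik_grouped(beta, _group(informative))


def fit_clogit(
    sets: Sequence[SetData],
    names: Optional[list[str]] = None,
    max_iter: int = 60,
    grad_tol: float = 1e-8,
    step_tol: float = 1e-8,
    beta_bound: float = 15.0,
) -> ConditionalLogisticFit:
    """Newton-Raphson fit of the conditional logistic model from b = 0
    with step-halving.

    Monotone likelihood (separation within sets) is detected when a
    coefficient passes ``beta_bound`` while its score stays one-signed;
    the fit is then flagged non-estimable rather than returned as a
    spurious finite estimate.
    """
    informative, dropped = _informative(sets)
    n_sets = len(sets)
    if not informative:
        raise EstimationError("no informative (outcome-discordant) matched sets")
    p = informative[0][0].shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]

    groups = _group(informative)
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grouped(beta, groups)
    n_iter = 0
    converged = False
    message = ""
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            message = "singular Hessian"
            break
        # step-halving
        accepted = False
        for _ in range(40):
            cand = beta + step
            ll_c, grad_c, hess_c = _loglik_grouped(cand, groups)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_c, grad_c, hess_c
                accepted = True
                break
            step /= 2.0
        if not accepted:
            message = "step-halving failed"
            break
        if np.max(np.abs(beta)) > beta_bound:
            cov = np.full((p, p), np.nan)
            return ConditionalLogisticFit(
                names, beta, cov, ll, n_iter, False, False,
                n_sets, len(informative), dropped,
                "monotone likelihood: separation within matched sets",
            )
        if np.max(np.abs(grad)) < grad_tol and np.max(np.abs(step)) < step_tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return ConditionalLogisticFit(
        names, beta, cov, ll, n_iter, converged, converged,
        n_sets, len(informative), dropped, message,
    )


# ---------------------------------------------------------------------------
# building sets from the analysis table

def build_analysis_sets(
    table: pd.DataFrame,
    irp_col: str,
    pc_cols: Sequence[str] = (),
    extra_cols: Sequence[str] = (),
) -> tuple[list[SetData], list[str]]:
    """Assemble (X, y) per matched set for one biomarker hypothesis.

    ``table`` needs set_id, treated (0/1), outcome (0/1) and ``irp_col``
    coded positive/negative (or 1/0).  Indeterminate-status and
    outcome-missing patients are excluded; sets reduced below two
    members are dropped here (and will not be informative anyway).
    """
    df = table.copy()
    if df[irp_col].dtype == object:
        df = df[df[irp_col].isin(["positive", "negative"])]
        df["_irp"] = (df[irp_col] == "positive").astype(float)
    else:
        df = df[df[irp_col].notna()]
        df["_irp"] = df[irp_col].astype(float)
    df = df[df["outcome"].notna()]
    names = ["treated", "irp", "treated:irp", *pc_cols, *extra_cols]
    sets: list[SetData] = []
    for _, grp in df.groupby("set_id", sort=True):
        if len(grp) < 2:
            continue
        t = grp["treated"].to_numpy(dtype=float)
        irp = grp["_irp"].to_numpy(dtype=float)
        cols = [t, irp, t * irp]
        cols += [grp[c].to_numpy(dtype=float) for c in pc_cols]
        cols += [grp[c].to_numpy(dtype=float) for c in extra_cols]
        X = np.column_stack(cols)
        y = grp["outcome"].to_numpy(dtype=float)
        sets.append((X, y))
    return sets, names


# ---------------------------------------------------------------------------
# tests and effect summaries

def interaction_test(
    fits: dict[str, ConditionalLogisticFit],
    spec: AnalysisSpec | None = None,
    term: str = "treated:irp",
    lrt_sets: Optional[dict[str, Sequence[SetData]]] = None,
) -> pd.DataFrame:
    """Wald test on the treatment-by-biomarker interaction, one row per
    IRP, at the Bonferroni per-test level.  Non-estimable fits are
    reported as inconclusive, never as significant."""
    sp = spec or AnalysisSpec()
    rows = []
    for irp_id in sorted(fits):
        fit = fits[irp_id]
        if not fit.estimable:
            rows.append({"irp_id": irp_id, "estimate": np.nan, "se": np.nan,
                         "z": np.nan, "p": np.nan, "significant": False,
                         "conclusive": False, "note": fit.message})
            continue
        est = fit.coef(term)
        se = fit.se(term)
        z = est / se if se > 0 else np.nan
        pval = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        row = {"irp_id": irp_id, "estimate": est, "se": se, "z": z, "p": pval,
               "significant": bool(np.isfinite(pval) and pval < sp.per_test_alpha),
               "conclusive": True, "note": ""}
        if lrt_sets is not None and irp_id in lrt_sets:
            row["p_lrt"] = _lrt_p(fit, lrt_sets[irp_id], term)
        rows.append(row)
    return pd.DataFrame(rows)


def _lrt_p(fit: ConditionalLogisticFit, sets: Sequence[SetData], term: str) -> float:
    j = fit.names.index(term)
    reduced = [(np.delete(X, j, axis=1), y) for X, y in sets]
    fit0 = fit_clogit(reduced, [n for i, n in enumerate(fit.names) if i != j])
    lr = 2 * (fit.loglik - fit0.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def subgroup_or(
    fit: ConditionalLogisticFit,
    treat_term: str = "treated",
    interaction_term: str = "treated:irp",
    level: float = 0.95,
) -> pd.DataFrame:
    """Treatment odds ratios within biomarker-negative (exp(b_treat))
    and biomarker-positive (exp(b_treat + b_interaction)) patients, with
    delta-method CIs from the coefficient covariance."""
    if not fit.estimable:
        raise EstimationError(f"fit not estimable: {fit.message}")
    i = fit.names.index(treat_term)
    j = fit.names.index(interaction_term)
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    b_neg = fit.beta[i]
    se_neg = np.sqrt(fit.cov[i, i])
    b_pos = fit.beta[i] + fit.beta[j]
    se_pos = np.sqrt(fit.cov[i, i] + fit.cov[j, j] + 2 * fit.cov[i, j])
    for stratum, b, se in (("negative", b_neg, se_neg), ("positive", b_pos, se_pos)):
        rows.append({
            "irp_stratum": stratum,
            "odds_ratio": float(np.exp(b)),
            "ci_lower": float(np.exp(b - z * se)),
            "ci_upper": float(np.exp(b + z * se)),
            "log_or": float(b),
            "se": float(se),
        })
    return pd.DataFrame(rows)


@dataclass
class ARREstimate:
    irp_stratum: str
    control_mortality: float
    treated_mortality: float
    arr: float                  # percentage points
    ci_lower: float
    ci_upper: float
    n_treated: int
    n_controls: int
    defined: bool = True
    note: str = ""


def weighted_arr(
    table: pd.DataFrame,
    irp_col: str,
    stratum: str,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> ARREstimate:
    """Absolute risk reduction in one biomarker stratum.

    Treated mortality is the plain mean over treated members of the
    stratum; control mortality weights each control 1/m_s by its set's
    control count, so each matched set contributes one control "unit".
    The CI is a seeded percentile bootstrap resampling whole matched
    sets (B = ``n_boot``), respecting the matched design.
    """
    df = table[table["outcome"].notna()].copy()
    if df[irp_col].dtype == object:
        df = df[df[irp_col] == stratum]
    else:
        want = 1.0 if stratum == "positive" else 0.0
        df = df[df[irp_col].astype(float) == want]
    m_per_set = (
        table[table["treated"] == 0].groupby("set_id")["patient_id"].count()
    )

    # per-set sufficient statistics (aligned over every matched set, so
    # the bootstrap resamples the full matched design)
    set_ids = sorted(table["set_id"].unique())
    pos = {s: i for i, s in enumerate(set_ids)}
    K = len(set_ids)
    nt = np.zeros(K)   # treated members in stratum
    dt = np.zeros(K)   # deaths among them
    wc = np.zeros(K)   # control weight mass (n_controls_in_stratum / m_s)
    wy = np.zeros(K)   # weighted control deaths
    for s, g in df.groupby("set_id"):
        i = pos[s]
        t = g[g["treated"] == 1]
        c = g[g["treated"] == 0]
        nt[i] = len(t)
        dt[i] = t["outcome"].sum()
        m_s = float(m_per_set.get(s, 0) or 1)
        wc[i] = len(c) / m_s
        wy[i] = c["outcome"].sum() / m_s

    n_treated = int(nt.sum())
    n_controls = int((df["treated"] == 0).sum())
    if nt.sum() == 0 or wc.sum() == 0:
        return ARREstimate(stratum, np.nan, np.nan, np.nan, np.nan, np.nan,
                           n_treated, n_controls, defined=False,
                           note="empty treated or control cell")
    treated_mort = float(dt.sum() / nt.sum())
    control_mort = float(wy.sum() / wc.sum())
    point = control_mort - treated_mort

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, K, size=(n_boot, K))
    nt_b = nt[idx].sum(axis=1)
    dt_b = dt[idx].sum(axis=1)
    wc_b = wc[idx].sum(axis=1)
    wy_b = wy[idx].sum(axis=1)
    ok = (nt_b > 0) & (wc_b > 0)
    boots = (wy_b[ok] / wc_b[ok]) - (dt_b[ok] / nt_b[ok])
    if boots.size:
        lo, hi = np.percentile(boots, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    else:
        lo = hi = np.nan
    return ARREstimate(
        irp_stratum=stratum,
        control_mortality=control_mort,
        treated_mortality=treated_mort,
        arr=100.0 * point,
        ci_lower=100.0 * float(lo),
        ci_upper=100.0 * float(hi),
        n_treated=n_treated,
        n_controls=n_controls,
    )
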