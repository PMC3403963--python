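"""Propensity model for treatment with drotrecogin alfa (activated).

The propensity score is the estimated probability that a patient would
have received the drug given baseline covariates: the Mahalanobis
matching variables (age, severity score standardized within score type,
four organ-dysfunction indicators, ventilation, medical/surgical
status, infection-site indicators) plus fixed-effect center indicators.
Five pre-specified age interactions are screened one at a time at the
0.05 level and retained jointly when significant.  The fitted scores
define a matching caliper of 0.6 sample standard deviations.

The maximum-likelihood fit is a Newton/IRLS iteration written here so
that separation and rank deficiency surface as first-class errors with
the offending covariate named.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MATCHING_SYSTEMS
from .config import StudyConfig
from .errors import SeparationError

#: Pre-specified interaction candidates (each an age x covariate product).
INTERACTION_CANDIDATES = (
    ("age", "severity_std"),
    ("age", "od_cardiovascular"),
    ("age", "od_pulmonary"),
    ("age", "od_coagulation"),
    ("age", "od_renal"),
)

INFECTION_SITE_DUMMIES = ("lung", "abdomen", "urinary")  # reference: other/unknown


@dataclass
class LogisticFit:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def wald_p(self, name: str) -> float:
        j = self.names.index(name)
        se = float(np.sqrt(self.cov[j, j]))
        if se == 0:
            return 1.0
        z = self.beta[j] / se
        return float(2 * stats.norm.sf(abs(z)))


@dataclass
class PropensityResult:
    scores: pd.Series                 # patient_id -> e in (0,1)
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    included_interactions: list[tuple[str, str]]
    score_sd: float
    caliper_width: float
    fit: LogisticFit = field(repr=False, default=None)


def logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta_bound: float = 15.0,
) -> LogisticFit:
    """Newton-Raphson logistic MLE with step-halving.

    Raises
    ------
    SeparationError
        When a coefficient diverges past ``beta_bound`` while the
        likelihood keeps climbing (monotone likelihood).
    np.linalg.LinAlgError wrapped as ValueError
        On rank-deficient designs, with the collinear columns listed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify dependent columns by greedy QR-style scan
        bad, kept = [], []
        for j in range(p):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        grad = X.T @ (y - mu)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        # step-halving on the log-likelihood
        ll_new = None
        for _ in range(30):
            cand = beta + step
            eta_c = np.clip(X @ cand, -500, 500)
            ll_c = float(y @ eta_c - np.sum(np.log1p(np.exp(eta_c))))
            if np.isfinite(ll_c) and ll_c >= ll_old - 1e-12:
                ll_new, beta = ll_c, cand
                break
            step /= 2.0
        if ll_new is None:
            break
        if np.max(np.abs(beta)) > beta_bound:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"separation detected: coefficient for {names[j]!r} diverging"
            )
        if np.max(np.abs(grad)) < tol * n or abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            w = np.clip(mu * (1 - mu), 1e-12, None)
            hess = X.T @ (X * w[:, None])
            return LogisticFit(names, beta, np.linalg.inv(hess), ll_old, it, True)
        ll_old = ll_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    hess = X.T @ (X * w[:, None])
    return LogisticFit(names, beta, np.linalg.inv(hess), ll_old, max_iter, False)


# ---------------------------------------------------------------------------
# design matrix

def base_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Main-effect covariate frame for the propensity model.

    Severity scores are standardized within score type so APACHE II and
    SAPS II cohorts pool into one column; organ dysfunctions enter as
    0/1 indicators; infection site as one-hot against 'other'.
    """
    cov = pd.DataFrame(index=records.index)
    cov["age"] = records["age"].astype(float)
    sev = records["severity_score"].astype(float)
    sev_std = pd.Series(np.nan, index=records.index)
    for stype, idx in records.groupby("severity_score_type").groups.items():
        vals = sev.loc[idx]
        sd = vals.std(ddof=1)
        sev_std.loc[idx] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    cov["severity_std"] = sev_std
    for s in MATCHING_SYSTEMS:
        cov[f"od_{s}"] = (records[f"od_{s}_present"] == True).astype(float)  # noqa: E712
    cov["ventilated"] = (records["ventilated"] == "yes").astype(float)
    cov["medical"] = (records["medical_surgical"] == "medical").astype(float)
    for site in INFECTION_SITE_DUMMIES:
        cov[f"site_{site}"] = (records["infection_site"] == site).astype(float)
    return cov


def center_dummies(records: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect center indicators, largest center as reference."""
    counts = records["center_id"].value_counts()
    reference = counts.index[0]
    out = pd.DataFrame(index=records.index)
    for center in sorted(c for c in counts.index if c != reference):
        out[f"center_{center}"] = (records["center_id"] == center).astype(float)
    return out


def _design(records: pd.DataFrame,
            interactions: list[tuple[str, str]]) -> tuple[np.ndarray, list[str]]:
    cov = base_covariates(records)
    cen = center_dummies(records)
    frames = [cov, cen]
    names = ["intercept"] + list(cov.columns) + list(cen.columns)
    X = np.column_stack(
        [np.ones(len(records))] + [f.to_numpy(dtype=float) for f in frames]
    )
    for a, b in interactions:
        col = cov[a].to_numpy() * cov[b].to_numpy()
        X = np.column_stack([X, col])
        names.append(f"{a}:{b}")
    return X, names


def screen_interactions(
    records: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Test each pre-specified age interaction one at a time on top of
    the main-effects model; retain those with two-sided Wald p < alpha.
    A candidate whose fit fails (separation, collinearity) is skipped
    with a log entry, never retained."""
    retained: list[tuple[str, str]] = []
    log: list[str] = []
    for cand in INTERACTION_CANDIDATES:
        X, names = _design(records, [cand])
        try:
            fit = logistic_mle(X, y, names)
            p = fit.wald_p(f"{cand[0]}:{cand[1]}")
        except (SeparationError, ValueError, np.linalg.LinAlgError) as exc:
            log.append(f"candidate {cand[0]}x{cand[1]} skipped: {exc}")
            continue
        if p < alpha:
            retained.append(cand)
            log.append(f"candidate {cand[0]}x{cand[1]} retained (p={p:.4g})")
        else:
            log.append(f"candidate {cand[0]}x{cand[1]} dropped (p={p:.4g})")
    return retained, log


def propensity_caliper_width(scores: np.ndarray | pd.Series, multiple: float) -> float:
    """Caliper = ``multiple`` x sample SD (ddof=1) of the fitted scores,
    on the probability scale."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores for a caliper")
    sd = float(np.std(scores, ddof=1))
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(scores)))):
        raise ValueError("degenerate caliper: propensity scores have zero variance")
    return multiple * sd


def fit_propensity(
    records: pd.DataFrame,
    config: StudyConfig | None = None,
    screen: bool = True,
) -> PropensityResult:
    """Fit the propensity model on the match-eligible population.

    ``records`` must have complete matching variables (post-imputation).
    Deterministic given the data: no randomness enters the fit.
    """
    cfg = config or StudyConfig()
    y = (records["treated"] == "treated").to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 treated and 2 control patients")
    interactions: list[tuple[str, str]] = []
    screen_log: list[str] = []
    if screen:
        interactions, screen_log = screen_interactions(
            records, y, cfg.interaction_screen_alpha
        )
    X, names = _design(records, interactions)
    fit = logistic_mle(X, y, names)
    eta = X @ fit.beta
    scores = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    if cfg.propensity_caliper_scale == "logit":
        caliper_basis = np.log(scores / (1 - scores))
    else:
        caliper_basis = scores
    sd = float(np.std(caliper_basis, ddof=1))
    width = propensity_caliper_width(caliper_basis, cfg.propensity_caliper_sd)
    ses = np.sqrt(np.diag(fit.cov))
    result = PropensityResult(
        scores=pd.Series(scores, index=records["patient_id"].to_numpy(), name="propensity"),
        coefficients=dict(zip(names, fit.beta.tolist())),
        standard_errors=dict(zip(names, ses.tolist())),
        included_interactions=interactions,
        score_sd=sd,
        caliper_width=width,
        fit=fit,
    )
    result.screen_log = screen_log  # type: ignore[attr-defined]
    return result
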