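"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, maxstat cutpoint.

cox_fit maximizes the partial likelihood by Newton-Raphson with
step-halving (Efron tie correction; Breslow by flag) and flags monotone
likelihood / non-convergence instead of failing silently.
maxstat_cutpoint searches all score thresholds keeping both groups above a
minimum fraction, maximizes the two-group log-rank statistic, and reports a
selection-corrected p-value from a permutation null of the maximal statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    times: np.ndarray            # distinct event times, ascending
    survival: np.ndarray         # S(t) at those times
    se: np.ndarray               # Greenwood standard errors
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("KM survival must be non-increasing")
        if ((self.survival < -1e-12) | (self.survival > 1 + 1e-12)).any():
            raise ValueError("KM survival outside [0, 1]")


def kaplan_meier(time, event) -> SurvivalFit:
    """Product-limit estimator with Greenwood variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if (time <= 0).any():
        raise ValueError("times must be > 0")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event must be binary 0/1")

    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    uniq = np.unique(t_sorted[e_sorted == 1])
    n = time.size
    surv, ses, at_risk, n_ev = [], [], [], []
    s = 1.0
    gw = 0.0  # Greenwood cumulative sum
    for t in uniq:
        r = int(np.sum(t_sorted >= t))
        d = int(np.sum((t_sorted == t) & (e_sorted == 1)))
        s *= (r - d) / r
        if r > d:
            gw += d / (r * (r - d))
            ses.append(s * np.sqrt(gw))
        else:
            ses.append(0.0)
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return SurvivalFit(
        times=uniq,
        survival=np.array(surv),
        se=np.array(ses),
        n_at_risk=np.array(at_risk),
        n_events=np.array(n_ev),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_chi2(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    """Two-group log-rank chi-square (df = 1); O - E over pooled event times."""
    order = np.argsort(time, kind="stable")
    t, e, g1 = time[order], event[order], in_group1[order].astype(float)
    n = t.size
    # tie-group starts
    starts = np.r_[0, 1 + np.flatnonzero(np.diff(t))]
    n_risk = n - starts
    n1_risk = np.cumsum(g1[::-1])[::-1][starts]
    d = np.add.reduceat(e.astype(float), starts)
    d1 = np.add.reduceat(e * g1, starts)
    keep = (d > 0) & (n_risk > 1)
    n_r, n1_r, d_r, d1_r = n_risk[keep], n1_risk[keep], d[keep], d1[keep]
    o_minus_e = float(np.sum(d1_r - d_r * n1_r / n_r))
    var = float(np.sum(d_r * (n1_r / n_r) * (1 - n1_r / n_r) * (n_r - d_r) / (n_r - 1)))
    if var <= 0:
        return 0.0
    return o_minus_e**2 / var


def logrank_test(time, event, group, n_permutations: int = 0, seed: int = 0) -> TestResult:
    """Two-group log-rank test; chi-square with 1 df.

    With ``n_permutations`` > 0 the p-value is instead the Monte-Carlo
    permutation tail probability of the statistic under group-label
    exchange (add-one corrected).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"logrank_test requires exactly 2 group levels, got {levels.tolist()}")
    if event.sum() == 0:
        raise ValueError("logrank_test requires at least 1 event")
    chi2 = _logrank_chi2(time, event, group == levels[0])
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = sum(
            _logrank_chi2(time, event, rng.permutation(group) == levels[0]) >= chi2 - 1e-12
            for _ in range(n_permutations)
        )
        p = (count + 1) / (n_permutations + 1)
        return TestResult(chi2, float(p), "logrank_permutation", df=1, n=time.size)
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(chi2, p, "logrank", df=1, n=time.size)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    converged: bool
    flagged: bool
    ties: str
    names: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hr": self.hazard_ratios,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "hr_ci_low": np.exp(self.ci_low),
                "hr_ci_high": np.exp(self.ci_high),
            },
            index=self.names or [f"x{i}" for i in range(len(self.beta))],
        )


def _cox_llgh(t, e, X, beta, ties):
    """Partial log-likelihood, gradient and information at beta.

    Arrays are pre-sorted by ascending time. Uses a fully vectorized path
    when event times are untied (Efron == Breslow there).
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilize exp; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    starts = np.r_[0, 1 + np.flatnonzero(np.diff(t))]
    group_of = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, n]))

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ev_idx = np.flatnonzero(e == 1)
    if ev_idx.size == 0:
        return ll, grad, info

    tied = False
    for gidx in np.unique(group_of[ev_idx]):
        if np.sum((group_of == gidx) & (e == 1)) > 1:
            tied = True
            break

    if not tied or ties == "breslow":
        first = starts[group_of[ev_idx]]
        s0e, s1e, s2e = s0[first], s1[first], s2[first]
        ll = float(np.sum(eta[ev_idx] - np.log(s0e)))
        xbar = s1e / s0e[:, None]
        grad = (X[ev_idx] - xbar).sum(axis=0)
        info = (s2e / s0e[:, None, None] - np.einsum("ij,ik->ijk", xbar, xbar)).sum(axis=0)
        return ll, grad, info

    # Efron with ties: loop over tie groups containing events
    for gidx in np.unique(group_of[ev_idx]):
        members = np.flatnonzero(group_of == gidx)
        D = members[e[members] == 1]
        d = D.size
        first = members[0]
        s0R, s1R, s2R = s0[first], s1[first], s2[first]
        s0D, s1D, s2D = w[D].sum(), wx[D].sum(axis=0), wxx[D].sum(axis=0)
        ll += float(eta[D].sum())
        grad += X[D].sum(axis=0)
        for j in range(d):
            f = j / d
            denom = s0R - f * s0D
            num1 = s1R - f * s1D
            num2 = s2R - f * s2D
            xbar = num1 / denom
            ll -= np.log(denom)
            grad -= xbar
            info += num2 / denom - np.outer(xbar, xbar)
    return ll, grad, info


def cox_fit(
    time,
    event,
    covariates,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox PH fit via Newton-Raphson on the partial likelihood.

    ``covariates`` may be a DataFrame, Series or array (n x p). Raises on
    constant covariates or when events < p + 1; flags (never silently
    accepts) non-convergence and likely monotone likelihood / separation.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(float)
    elif isinstance(covariates, pd.Series):
        names = [str(covariates.name or "x0")]
        X = covariates.to_numpy(float)[:, None]
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if time.size != n or event.size != n:
        raise ValueError("time/event/covariate lengths disagree")
    const = np.flatnonzero(X.std(axis=0) == 0)
    if const.size:
        raise ValueError(f"constant covariate(s): {[names[i] for i in const]}")
    n_ev = int(event.sum())
    if n_ev < p + 1:
        raise ValueError(f"{n_ev} events insufficient for {p} covariate(s)")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")

    center = X.mean(axis=0)
    Xc = X - center
    order = np.argsort(time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], Xc[order]

    beta = np.zeros(p)
    ll, grad, info = _cox_llgh(t_s, e_s, X_s, beta, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving: never accept a decrease in log-likelihood
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _cox_llgh(t_s, e_s, X_s, cand, ties)
            if ll_new >= ll - 1e-14:
                break
            factor /= 2.0
        if ll_new < ll:
            break
        delta_ll = ll_new - ll
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if abs(delta_ll) < tol:
            converged = True
            break

    flagged = (not converged) or bool(np.abs(beta).max() > 15)
    if flagged:
        logger.warning("cox_fit: flagged (converged=%s, max|beta|=%.3g)", converged, np.abs(beta).max())
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flagged = True
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(0.975)
    return CoxFit(
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        ci_low=beta - zcrit * se,
        ci_high=beta + zcrit * se,
        loglik=ll,
        converged=converged,
        flagged=flagged,
        ties=ties,
        names=names,
        n=n,
        n_events=n_ev,
    )


# ---------------------------------------------------------------------------
# maximally selected log-rank cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    threshold: float
    statistic: float
    p_value: float | None
    candidates: np.ndarray
    statistics: np.ndarray
    n_low: int
    n_high: int
    n_permutations: int


def _max_logrank(time, event, score, candidates) -> tuple[int, float, np.ndarray]:
    stats_ = np.array([
        _logrank_chi2(time, event, score <= v) for v in candidates
    ])
    best = int(np.argmax(stats_))
    return best, float(stats_[best]), stats_


def maxstat_cutpoint(
    time,
    event,
    score,
    min_frac: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutpointResult:
    """Best log-rank split of a continuous score.

    Candidate thresholds are the unique score values whose low/high split
    keeps both groups at size >= min_frac * n. The returned p-value is the
    permutation tail probability of the maximal statistic (None when
    ``n_permutations`` is 0).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    score = np.asarray(score, float)
    n = score.size
    if not (0 < min_frac < 0.5):
        raise ValueError("min_frac must lie in (0, 0.5)")
    uniq = np.unique(score)
    min_n = int(np.ceil(min_frac * n))
    cand = np.array([v for v in uniq
                     if min_n <= np.sum(score <= v) <= n - min_n])
    if cand.size == 0:
        raise ValueError("no valid cutpoint candidate under min_frac constraint")

    best, stat, stats_ = _max_logrank(time, event, score, cand)
    threshold = float(cand[best])
    n_low = int(np.sum(score <= threshold))

    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            # permuting scores preserves the score multiset, so the candidate
            # threshold set is unchanged
            perm = rng.permutation(score)
            _, stat_p, _ = _max_logrank(time, event, perm, cand)
            if stat_p >= stat:
                count += 1
        p = (count + 1) / (n_permutations + 1)

    logger.info("maxstat: threshold=%.4g, chi2=%.3f, groups %d/%d", threshold, stat,
                n_low, n - n_low)
    return CutpointResult(
        threshold=threshold,
        statistic=stat,
        p_value=p,
        candidates=cand,
        statistics=stats_,
        n_low=n_low,
        n_high=n - n_low,
        n_permutations=n_permutations,
    )
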