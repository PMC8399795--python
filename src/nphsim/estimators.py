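"""Regression-based treatment-effect estimators.

Each fitter returns an :class:`EstimateResult` on the reported scale (HR and TR
multiplicative, dRMST in months) with the standard error on the inference
scale (log for HR/TR), a 95% Wald interval and a two-sided p-value.  Cox and
landmark fits are delegated to lifelines (Efron ties); the piecewise
exponential model is a Poisson GLM on episode-split data with a log
person-time offset (statsmodels); the Weibull model is fitted by full maximum
likelihood in either the proportional-hazards or the accelerated-failure-time
parameterisation, whose coefficients satisfy beta_PH = -beta_AFT * gamma.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scenarios import TrialDataset

logger = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)

PE_DEFAULT_CUTPOINTS = (1.0, 3.0, 10.0, 20.0)


@dataclass
class EstimateResult:
    method: str  # cox, lm, pe1, pe2, weibull_aft, weibull_ph, rp_ph, rp_td
    estimand: str  # HR, TR, dRMST
    point: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events_used: int
    converged: bool = True
    log_point: float | None = None  # log HR / log TR; None for dRMST
    extra: dict = field(default_factory=dict)


def _failed(method: str, estimand: str, n_events: int = 0) -> EstimateResult:
    nan = float("nan")
    return EstimateResult(method, estimand, nan, nan, nan, nan, nan, n_events, False, nan)


def _ratio_result(
    method: str, estimand: str, log_point: float, se: float, n_events: int
) -> EstimateResult:
    z = log_point / se
    return EstimateResult(
        method=method,
        estimand=estimand,
        point=math.exp(log_point),
        se=se,
        ci_low=math.exp(log_point - Z975 * se),
        ci_high=math.exp(log_point + Z975 * se),
        p_value=2.0 * stats.norm.sf(abs(z)),
        n_events_used=n_events,
        converged=True,
        log_point=log_point,
    )


# ---------------------------------------------------------------------------
# Cox / landmark
# ---------------------------------------------------------------------------


def fit_cox(data: TrialDataset, landmark_time: float = 0.0) -> EstimateResult:
    """Cox PH fit; with landmark_time > 0, conditional on being event-free then.

    Subjects with time <= landmark_time are discarded (their events contribute
    nothing); the time origin is not reset, which leaves the partial likelihood
    unchanged because risk sets are preserved.
    """
    from lifelines import CoxPHFitter

    method = "lm" if landmark_time > 0 else "cox"
    keep = data.time > landmark_time
    arm, time, event = data.arm[keep], data.time[keep], data.event[keep]
    n_events = int(event.sum())
    if n_events == 0 or event[arm == 1].sum() == 0 or event[arm == 0].sum() == 0:
        return _failed(method, "HR", n_events)
    df = pd.DataFrame({"time": time, "event": event.astype(int), "arm": arm.astype(int)})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:  # convergence failure
        return _failed(method, "HR", n_events)
    beta = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    res = _ratio_result(method, "HR", beta, se, n_events)
    res.extra["landmark_time"] = landmark_time
    return res


def cox_partial_loglik(beta: float, time, event, arm, ties: str = "efron") -> float:
    """Partial log-likelihood for a single binary covariate (oracle-friendly).

    Written directly from the risk-set definition so it can serve as an
    independent check on library fits.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    arm = np.asarray(arm, int)
    ll = 0.0
    eb = math.exp(beta)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        d1 = int((dead & (arm == 1)).sum())
        r1 = int((at_risk & (arm == 1)).sum())
        r0 = int(at_risk.sum()) - r1
        ll += beta * d1
        if ties == "breslow":
            ll -= d * math.log(r0 + r1 * eb)
        else:  # efron
            for l in range(d):
                ll -= math.log(r0 + r1 * eb - (l / d) * ((d - d1) + d1 * eb))
    return ll


def _risk_counts(time, event, arm):
    """Aggregated risk-set counts at distinct event times (sorted ascending)."""
    order = np.argsort(time, kind="stable")
    t, e, a = time[order], event[order], arm[order]
    n = len(t)
    ut, start = np.unique(t, return_index=True)
    # at risk just before each distinct time = subjects with time >= that time
    nrisk = n - start
    n1risk = np.concatenate([np.cumsum(a[::-1])[::-1], [0]])[start]
    d = np.add.reduceat(e.astype(float), start)
    d1 = np.add.reduceat((e * a).astype(float), start)
    ev = d > 0
    return ut[ev], nrisk[ev].astype(float), n1risk[ev].astype(float), d[ev], d1[ev]


def fast_cox_binary(time, event, arm, max_iter: int = 30, tol: float = 1e-10):
    """Newton-Raphson Cox fit for one binary covariate (Breslow ties).

    Returns (beta, se).  Used inside permutation loops where a full model
    object per fit would dominate the runtime; with continuous event times
    ties have probability zero so Breslow and Efron coincide.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, np.int64)
    arm = np.asarray(arm, np.int64)
    _, nrisk, n1, d, d1 = _risk_counts(time, event, arm)
    n0 = nrisk - n1
    beta = 0.0
    for _ in range(max_iter):
        eb = math.exp(beta)
        denom = n0 + n1 * eb
        mu = n1 * eb / denom
        score = float(np.sum(d1 - d * mu))
        info = float(np.sum(d * mu * (1.0 - mu)))
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    eb = math.exp(beta)
    mu = n1 * eb / (n0 + n1 * eb)
    info = float(np.sum(d * mu * (1.0 - mu)))
    se = math.sqrt(1.0 / info) if info > 0 else float("nan")
    return beta, se


# ---------------------------------------------------------------------------
# piecewise exponential
# ---------------------------------------------------------------------------


def split_episodes(data: TrialDataset, cutpoints) -> pd.DataFrame:
    """Episode-split a trial at the given interior cutpoints.

    Returns one row per (subject, interval) with positive person-time and the
    event count in that interval; the likelihood of the piecewise exponential
    model on these rows equals a Poisson log-linear model with log person-time
    offset.
    """
    cuts = np.asarray(sorted(cutpoints), float)
    horizon = float(data.time.max())
    if np.any(cuts <= 0) or np.any(cuts >= horizon):
        raise ValueError("cutpoints must lie strictly inside (0, max follow-up)")
    lower = np.concatenate([[0.0], cuts])
    upper = np.concatenate([cuts, [np.inf]])
    rows = []
    for j, (lo, hi) in enumerate(zip(lower, upper)):
        pt = np.clip(np.minimum(data.time, hi) - lo, 0.0, None)
        ev = ((data.time > lo) & (data.time <= hi) & (data.event == 1)).astype(int)
        keep = pt > 0
        if not np.any(keep):
            logger.warning("piecewise interval %d [%g, %g) has no person-time; dropped", j, lo, hi)
            continue
        rows.append(
            pd.DataFrame(
                {
                    "interval": j,
                    "start": lo,
                    "arm": data.arm[keep].astype(int),
                    "persontime": pt[keep],
                    "events": ev[keep],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fit_piecewise_exponential(
    data: TrialDataset,
    cutpoints=PE_DEFAULT_CUTPOINTS,
    period_specific_from: float | None = None,
):
    """Piecewise exponential HR via Poisson GLM on episode-split data.

    Without ``period_specific_from`` returns the single summary HR (PE1).
    With it, a treatment-by-period interaction is added at t_PE and a list of
    two results is returned: the HR from events at or before t_PE and the HR
    from events after it (the latter is the canonical PE2 summary).
    """
    import statsmodels.api as sm

    n_events = data.n_events
    if data.event[data.arm == 1].sum() == 0 or data.event[data.arm == 0].sum() == 0:
        failed = _failed("pe2" if period_specific_from else "pe1", "HR", n_events)
        return [failed, failed] if period_specific_from else failed

    cuts = set(float(c) for c in cutpoints)
    if period_specific_from is not None:
        cuts.add(float(period_specific_from))
    long = split_episodes(data, sorted(cuts))

    X = pd.get_dummies(long["interval"], prefix="iv", drop_first=False).astype(float)
    if period_specific_from is None:
        X["arm"] = long["arm"].astype(float)
        names = ["arm"]
        method = "pe1"
    else:
        post = (long["start"] >= period_specific_from).astype(float)
        X["arm_pre"] = long["arm"] * (1.0 - post)
        X["arm_post"] = long["arm"] * post
        names = ["arm_pre", "arm_post"]
        method = "pe2"
    model = sm.GLM(
        long["events"].to_numpy(),
        X.to_numpy(),
        family=sm.families.Poisson(),
        offset=np.log(long["persontime"].to_numpy()),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit()
    except Exception:
        failed = _failed(method, "HR", n_events)
        return [failed, failed] if period_specific_from else failed

    cols = list(X.columns)
    results = []
    for name in names:
        i = cols.index(name)
        res = _ratio_result(method, "HR", float(fit.params[i]), float(fit.bse[i]), n_events)
        res.extra["term"] = name
        results.append(res)
    return results if period_specific_from is not None else results[0]


# ---------------------------------------------------------------------------
# Weibull PH / AFT maximum likelihood
# ---------------------------------------------------------------------------


def _weibull_negloglik_ph(theta, logt, event, arm):
    loglam, loggam, beta = theta
    lam, gam = math.exp(loglam), math.exp(loggam)
    logh = loglam + loggam + (gam - 1.0) * logt + beta * arm
    H = lam * np.exp(gam * logt + beta * arm)
    return -(np.sum(event * logh) - np.sum(H))


def _weibull_negloglik_aft(theta, logt, event, arm):
    mu, logsig, b = theta
    sig = math.exp(logsig)
    z = (logt - mu - b * arm) / sig
    # hazard h(t) = exp(z)/(sigma*t); survival S = exp(-exp(z))
    return -(np.sum(event * (z - logsig - logt)) - np.sum(np.exp(z)))


def _fd_hessian(fun, x, args=(), eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; adequate for smooth likelihoods."""
    x = np.asarray(x, float)
    p = len(x)
    H = np.empty((p, p))
    f0 = fun(x, *args)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(x + ei + ej, *args)
            fpm = fun(x + ei - ej, *args)
            fmp = fun(x - ei + ej, *args)
            fmm = fun(x - ei - ej, *args)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    return H


def _mle(negloglik, theta0, args):
    res = optimize.minimize(
        negloglik, theta0, args=args, method="BFGS", options={"gtol": 1e-10, "maxiter": 500}
    )
    # polish with one or two Newton steps for tight parameterisation invariance
    theta = res.x
    for _ in range(3):
        g = optimize.approx_fprime(theta, negloglik, 1e-8, *args)
        H = _fd_hessian(negloglik, theta, args)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        theta = theta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    H = _fd_hessian(negloglik, theta, args)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return theta, None, False
    # convergence judged at the polished point, not by the BFGS status flag
    g = optimize.approx_fprime(theta, negloglik, 1e-8, *args)
    ok = bool(
        np.all(np.isfinite(cov))
        and np.all(np.diag(cov) > 0)
        and np.max(np.abs(g)) < 1e-3 * max(1.0, abs(negloglik(theta, *args)))
    )
    return theta, cov, ok


def fit_weibull(data: TrialDataset, parameterisation: str = "aft") -> EstimateResult:
    """Weibull MLE with a treatment covariate.

    parameterisation "ph": h(t) = lambda*gamma*t**(gamma-1)*exp(beta*arm),
    reported as HR = exp(beta).  "aft": log t = mu + b*arm + sigma*W (extreme
    value W), reported as TR = exp(b).  The two maxima are related by
    beta_PH = -b_AFT * gamma.
    """
    if parameterisation not in {"ph", "aft"}:
        raise ValueError("parameterisation must be 'ph' or 'aft'")
    n_events = data.n_events
    if n_events == 0 or data.event[data.arm == 1].sum() == 0 or data.event[data.arm == 0].sum() == 0:
        return _failed(f"weibull_{parameterisation}", "HR" if parameterisation == "ph" else "TR", n_events)
    logt = np.log(data.time)
    event = data.event.astype(float)
    arm = data.arm.astype(float)
    if parameterisation == "ph":
        rate = n_events / float(np.sum(data.time))
        theta0 = np.array([math.log(rate), 0.0, 0.0])
        theta, cov, ok = _mle(_weibull_negloglik_ph, theta0, (logt, event, arm))
        method, estimand = "weibull_ph", "HR"
        shape = math.exp(theta[1])
    else:
        theta0 = np.array([float(np.mean(logt)), 0.0, 0.0])
        theta, cov, ok = _mle(_weibull_negloglik_aft, theta0, (logt, event, arm))
        method, estimand = "weibull_aft", "TR"
        shape = 1.0 / math.exp(theta[1])
    if not ok or cov is None:
        return _failed(method, estimand, n_events)
    coef = float(theta[2])
    se = float(math.sqrt(cov[2, 2]))
    res = _ratio_result(method, estimand, coef, se, n_events)
    res.extra["shape"] = shape  # gamma-hat
    res.extra["theta"] = theta
    return res
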