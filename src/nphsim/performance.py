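"""Monte Carlo performance measures benchmarked against the trial design.

Power is the proportion of replicates with p < alpha; the scaled treatment
effect (STE) rescales the mean estimate so 100% is the full design effect and
0% is no effect; coverage is the proportion of 95% intervals containing the
design-model value.  Monte Carlo standard errors are sqrt(p(1-p)/n_sims).
The design benchmark also carries the required number of events from the
Freedman logrank sample-size formula and an empirical dRMST_design from a
large single simulation of the design cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scenarios import DESIGN_LOG_HR, HORIZON, design_scenario, sample_trial
from .survtests import km_rmst

ALPHA = 0.05


def required_events(
    hr: float, alpha: float = 0.05, power: float = 0.80, allocation_ratio: float = 1.0
) -> int:
    """Required number of events for the logrank test, Freedman's formula.

    d = ceil( ((1 + phi*hr)/(1 - hr))^2 * (z_{1-a/2} + z_power)^2 / phi )
    with allocation ratio phi (1 for 1:1 allocation).  A superiority framing
    is assumed: hr must lie in (0, 1).
    """
    if not 0.0 < hr < 1.0:
        raise ValueError("hr must lie in (0, 1) for a superiority design")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    phi = allocation_ratio
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    d = ((1.0 + phi * hr) / (1.0 - hr)) ** 2 * z * z / phi
    return int(math.ceil(d))


def monte_carlo_se(p: float, n_sims: int) -> float:
    """MCSE of an estimated proportion: sqrt(p(1-p)/n); maximal at p = 0.5."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    return math.sqrt(p * (1.0 - p) / n_sims)


def compute_power(p_values, alpha: float = ALPHA) -> tuple[float, float]:
    """Percentage of replicates with p < alpha, with its MCSE (both in %)."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no p-values supplied")
    frac = float(np.mean(p < alpha))
    return 100.0 * frac, 100.0 * monte_carlo_se(frac, len(p))


@dataclass
class DesignBenchmark:
    """Design-model quantities all scenarios are benchmarked against."""

    beta_design: float = DESIGN_LOG_HR
    alpha: float = ALPHA
    power_design: float = 0.80
    drmst_design: float = float("nan")  # months, estimated empirically
    drmst_design_se: float = float("nan")
    required_events: int = field(default=0)

    @property
    def hr_design(self) -> float:
        return math.exp(self.beta_design)

    @property
    def tr_design(self) -> float:
        # under the exponential design cell (gamma = 1), TR = exp(-beta/gamma)
        return math.exp(-self.beta_design)


def design_benchmark(
    n_large: int = 250_000, seed: int | np.random.Generator = 0
) -> DesignBenchmark:
    """Empirical benchmark from one large simulation of the design cell.

    dRMST_design is the nonparametric (KM-integral) restricted mean difference
    at t* = 50 months, model-free by construction.
    """
    if n_large < 10_000:
        raise ValueError("n_large must be at least 10,000 for a stable benchmark")
    scen = design_scenario(n_subjects=n_large)
    trial = sample_trial(scen, seed)
    r1, v1 = km_rmst(trial.time[trial.arm == 1], trial.event[trial.arm == 1], HORIZON)
    r0, v0 = km_rmst(trial.time[trial.arm == 0], trial.event[trial.arm == 0], HORIZON)
    bench = DesignBenchmark(
        drmst_design=r1 - r0,
        drmst_design_se=math.sqrt(v1 + v0),
        required_events=required_events(math.exp(DESIGN_LOG_HR), ALPHA, 0.80),
    )
    return bench


def compute_ste(estimates, estimand: str, benchmark: DesignBenchmark) -> float:
    """Scaled treatment effect in percent.

    HR:    (1 - mean[HR]) / (1 - HR_design) * 100
    TR:    (mean[TR] - 1) / (TR_design - 1) * 100
    dRMST: mean[dRMST] / dRMST_design * 100
    """
    pts = np.asarray([e.point for e in estimates if e.converged], float)
    if len(pts) == 0:
        return float("nan")
    for e in estimates:
        if e.converged and e.estimand != estimand:
            raise ValueError(f"estimand mismatch: expected {estimand}, got {e.estimand}")
    m = float(np.mean(pts))
    if estimand == "HR":
        return (1.0 - m) / (1.0 - benchmark.hr_design) * 100.0
    if estimand == "TR":
        return (m - 1.0) / (benchmark.tr_design - 1.0) * 100.0
    if estimand == "dRMST":
        return m / benchmark.drmst_design * 100.0
    raise ValueError(f"unknown estimand {estimand!r}")


def _design_value(estimand: str, benchmark: DesignBenchmark, scale: str) -> float:
    if estimand == "HR":
        return benchmark.beta_design if scale == "log" else benchmark.hr_design
    if estimand == "TR":
        return -benchmark.beta_design if scale == "log" else benchmark.tr_design
    if estimand == "dRMST":
        return benchmark.drmst_design
    raise ValueError(f"unknown estimand {estimand!r}")


def compute_coverage(estimates, estimand: str, benchmark: DesignBenchmark) -> tuple[float, float]:
    """Percentage of 95% intervals containing the design value, with MCSE.

    Ratio estimands are compared on the log scale (the inference scale);
    dRMST in months against the empirical design benchmark.
    """
    target_rep = _design_value(estimand, benchmark, scale="reported")
    hits = []
    for e in estimates:
        if not e.converged:
            continue
        if e.estimand != estimand:
            raise ValueError(f"estimand mismatch: expected {estimand}, got {e.estimand}")
        hits.append(e.ci_low <= target_rep <= e.ci_high)
    if not hits:
        return float("nan"), float("nan")
    frac = float(np.mean(hits))
    return 100.0 * frac, 100.0 * monte_carlo_se(frac, len(hits))


@dataclass
class PerformanceSummary:
    scenario_id: str
    method: str
    estimand: str
    n_sims: int
    n_nonconverged: int
    power_pct: float
    mcse_power: float
    ste_pct: float
    coverage_pct: float
    mcse_coverage: float
    mean_point: float


def summarise_fits(
    estimates_by_key: dict, benchmark: DesignBenchmark, alpha: float = ALPHA
) -> pd.DataFrame:
    """Tidy per-(scenario, method, estimand) summary table.

    ``estimates_by_key`` maps (scenario_id, method, estimand) to the list of
    per-replicate EstimateResults.  Non-converged replicates are excluded from
    every numerator and denominator and counted explicitly.
    """
    rows = []
    for (sid, method, estimand), ests in sorted(estimates_by_key.items()):
        ok = [e for e in ests if e.converged]
        n_bad = len(ests) - len(ok)
        if not ok:
            rows.append(
                PerformanceSummary(sid, method, estimand, 0, n_bad, *(float("nan"),) * 5, float("nan"))
            )
            continue
        power, mcse_p = compute_power([e.p_value for e in ok], alpha)
        cov, mcse_c = compute_coverage(ok, estimand, benchmark)
        ste = compute_ste(ok, estimand, benchmark)
        mean_point = float(np.mean([e.point for e in ok]))
        rows.append(
            PerformanceSummary(
                sid, method, estimand, len(ok), n_bad, power, mcse_p, ste, cov, mcse_c, mean_point
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def summarise_tests(results_by_key: dict, alpha: float = ALPHA) -> pd.DataFrame:
    """Rejection-rate table for tests: (scenario_id, test_name) -> TestResults."""
    rows = []
    for (sid, name), results in sorted(results_by_key.items()):
        power, mcse = compute_power([r.p_value for r in results], alpha)
        rows.append(
            {
                "scenario_id": sid,
                "test_name": name,
                "n_sims": len(results),
                "power_pct": power,
                "mcse_power": mcse,
            }
        )
    return pd.DataFrame(rows)
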