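"""Scenario grid and data generation for two-arm survival trials.

The data-generating model is a Weibull baseline hazard h0(t) = lambda * gamma *
t**(gamma - 1) with a two-period piecewise treatment hazard ratio: either a lag
until the treatment becomes effective (HR = 1 for t <= t_lag, HR = exp(beta)
after) or an early effect that ceases (HR = exp(beta) for t <= t_early, HR = 1
after).  All subjects enter at t = 0 and are administratively censored at the
study horizon.  Event times are drawn by inverse-transform sampling of the
closed-form piecewise cumulative hazard, so the simulator follows the analytic
survival law exactly.

Three baseline shapes are used: decreasing (lambda=0.15, gamma=0.9), constant
(lambda=0.10, gamma=1.0) and increasing (lambda=0.07, gamma=1.1), calibrated so
that control-arm survival at the horizon t=50 months is (nearly) the same under
all three, i.e. the same expected number of events with only their timing
differing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventRateSpec",
    "EffectProfile",
    "ScenarioSpec",
    "TrialDataset",
    "DECREASING",
    "CONSTANT",
    "INCREASING",
    "CANONICAL_RATES",
    "HORIZON",
    "DESIGN_LOG_HR",
    "cumulative_hazard",
    "survival_probability",
    "sample_trial",
    "expected_event_fraction_before",
    "scenario_grid",
    "design_scenario",
    "write_trials_csv",
    "read_trials_csv",
]

HORIZON = 50.0
DESIGN_LOG_HR = -0.4
N_SUBJECTS_DEFAULT = 207  # smallest n with >= 202 expected events in the design cell


@dataclass(frozen=True)
class EventRateSpec:
    """Weibull baseline hazard: h0(t) = scale * shape * t**(shape-1)."""

    label: str
    scale: float  # lambda, per month**shape
    shape: float  # gamma

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")


DECREASING = EventRateSpec("decreasing", 0.15, 0.9)
CONSTANT = EventRateSpec("constant", 0.10, 1.0)
INCREASING = EventRateSpec("increasing", 0.07, 1.1)
CANONICAL_RATES = (DECREASING, CONSTANT, INCREASING)


@dataclass(frozen=True)
class EffectProfile:
    """Piecewise treatment effect on the hazard scale.

    kind:
        "ph"    -- HR = exp(log_hr_active) at all times
        "lag"   -- HR = 1 for t <= change_time, exp(log_hr_active) after
        "early" -- HR = exp(log_hr_active) for t <= change_time, 1 after
        "null"  -- HR = 1 at all times
    """

    kind: str
    change_time: float = 0.0
    log_hr_active: float = DESIGN_LOG_HR

    def __post_init__(self) -> None:
        if self.kind not in {"ph", "lag", "early", "null"}:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.change_time < 0:
            raise ValueError("change_time must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    rate: EventRateSpec
    effect: EffectProfile
    horizon: float = HORIZON
    n_subjects: int = N_SUBJECTS_DEFAULT
    allocation_prob: float = 0.5
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive integer")
        if not 0.0 < self.allocation_prob < 1.0:
            raise ValueError("allocation_prob must lie in (0, 1)")


@dataclass
class TrialDataset:
    """One simulated (or externally supplied) two-arm trial.

    ``event == 0`` means administrative censoring at the horizon, in which case
    ``time`` equals the horizon exactly.
    """

    arm: np.ndarray
    time: np.ndarray
    event: np.ndarray
    scenario: ScenarioSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=np.int8)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        if not (len(self.arm) == len(self.time) == len(self.event)):
            raise ValueError("arm, time, event must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_dataframe(self) -> pd.DataFrame:
        sid = self.scenario.scenario_id if self.scenario is not None else ""
        return pd.DataFrame(
            {
                "subject_id": np.arange(len(self), dtype=int),
                "arm": self.arm.astype(int),
                "time": self.time,
                "event": self.event.astype(int),
                "scenario_id": sid,
                "seed": self.seed if self.seed is not None else -1,
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, scenario: ScenarioSpec | None = None
    ) -> "TrialDataset":
        seed = None
        if "seed" in df.columns and len(df) and df["seed"].iloc[0] >= 0:
            seed = int(df["seed"].iloc[0])
        return cls(
            arm=df["arm"].to_numpy(),
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            scenario=scenario,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def cumulative_hazard(scenario: ScenarioSpec, arm: int, t) -> np.ndarray | float:
    """Closed-form cumulative hazard H_arm(t), piecewise across the change point.

    Continuous and non-decreasing in t; H(0) = 0.  For the control arm this is
    the plain Weibull lambda * t**gamma.
    """
    t = _check_time(t)
    lam, gam = scenario.rate.scale, scenario.rate.shape
    base = lam * t**gam
    if arm == 0:
        return base if base.ndim else float(base)
    eff = scenario.effect
    if eff.kind == "null":
        h = base
    elif eff.kind == "ph":
        h = math.exp(eff.log_hr_active) * base
    elif eff.kind == "lag":
        c = eff.change_time
        hc = lam * c**gam
        hr = math.exp(eff.log_hr_active)
        h = np.where(t <= c, base, hc + hr * (base - hc))
    else:  # early
        c = eff.change_time
        hr = math.exp(eff.log_hr_active)
        hc = hr * lam * c**gam
        h = np.where(t <= c, hr * base, hc + (base - lam * c**gam))
    return h if h.ndim else float(h)


def survival_probability(scenario: ScenarioSpec, arm: int, t) -> np.ndarray | float:
    """S_arm(t) = exp(-H_arm(t))."""
    h = cumulative_hazard(scenario, arm, t)
    return np.exp(-np.asarray(h)) if np.ndim(h) else math.exp(-h)


def _invert_cumhaz(scenario: ScenarioSpec, arm: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Solve H_arm(t) = u for t, vectorised over subjects (u = -ln U)."""
    lam, gam = scenario.rate.scale, scenario.rate.shape
    eff = scenario.effect
    t0 = (u / lam) ** (1.0 / gam)  # control-arm solution
    out = t0.copy()
    trt = arm == 1
    if not np.any(trt):
        return out
    if eff.kind == "null":
        return out
    hr = math.exp(eff.log_hr_active)
    if eff.kind == "ph":
        out[trt] = (u[trt] / (lam * hr)) ** (1.0 / gam)
    elif eff.kind == "lag":
        c = eff.change_time
        hc = lam * c**gam
        ut = u[trt]
        late = ut > hc
        tt = t0[trt]
        tt[late] = (c**gam + (ut[late] - hc) / (lam * hr)) ** (1.0 / gam)
        out[trt] = tt
    else:  # early
        c = eff.change_time
        hc = hr * lam * c**gam
        ut = u[trt]
        tt = (ut / (lam * hr)) ** (1.0 / gam)
        late = ut > hc
        tt[late] = (c**gam + (ut[late] - hc) / lam) ** (1.0 / gam)
        out[trt] = tt
    return out


def sample_trial(
    scenario: ScenarioSpec, seed: int | np.random.Generator | np.random.SeedSequence
) -> TrialDataset:
    """Draw one trial by inverse-transform sampling of the piecewise hazard.

    Arms are Bernoulli(allocation_prob); a subject whose latent event time
    exceeds the horizon is administratively censored there.
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_rec = seed, None
    else:
        rng = np.random.default_rng(seed)
        seed_rec = int(seed) if isinstance(seed, (int, np.integer)) else None
    n = scenario.n_subjects
    arm = rng.binomial(1, scenario.allocation_prob, size=n).astype(np.int8)
    u = -np.log(rng.uniform(size=n))
    t = _invert_cumhaz(scenario, arm, u)
    event = (t < scenario.horizon).astype(np.int8)
    time = np.where(event == 1, t, scenario.horizon)
    return TrialDataset(arm=arm, time=time, event=event, scenario=scenario, seed=seed_rec)


def expected_event_fraction_before(scenario: ScenarioSpec) -> float:
    """Expected fraction of observed events occurring at or before the change time.

    Pooled over arms with the allocation weights:
    [p0*F_0(c) + p1*F_1(c)] / [p0*F_0(h) + p1*F_1(h)] with F = 1 - S evaluated
    in closed form.  Defined only for lag and early profiles; for an early
    profile the no-effect period is *after* the change time, so its expected
    no-effect fraction is one minus this value.
    """
    eff = scenario.effect
    if eff.kind not in {"lag", "early"}:
        raise ValueError("event fraction is defined only for lag/early profiles")
    c, h = eff.change_time, scenario.horizon
    p1 = scenario.allocation_prob
    p0 = 1.0 - p1

    def frac(t: float) -> float:
        return p0 * (1.0 - survival_probability(scenario, 0, t)) + p1 * (
            1.0 - survival_probability(scenario, 1, t)
        )

    return frac(min(c, h)) / frac(h)


# ---------------------------------------------------------------------------
# scenario grid
# ---------------------------------------------------------------------------

LAG_TIMES = (0.0, 1.0, 3.0, 10.0)
EARLY_TIMES = (3.0, 10.0, 20.0, 50.0)


def design_scenario(n_subjects: int = N_SUBJECTS_DEFAULT) -> ScenarioSpec:
    """The design cell: constant event rate, proportional hazards, beta = -0.4."""
    return ScenarioSpec(
        rate=CONSTANT,
        effect=EffectProfile("ph", 0.0, DESIGN_LOG_HR),
        n_subjects=n_subjects,
        scenario_id="design_ph",
    )


def scenario_grid(n_subjects: int = N_SUBJECTS_DEFAULT) -> list[ScenarioSpec]:
    """The full study grid.

    3 rates x 4 lag times (t_lag = 0 are PH cells), 3 rates x 4 early-effect
    times (t_early = 50 are PH cells), plus one null (beta = 0) cell per rate
    for Type I error: 27 scenarios in total.
    """
    grid: list[ScenarioSpec] = []
    for rate in CANONICAL_RATES:
        for c in LAG_TIMES:
            grid.append(
                ScenarioSpec(
                    rate=rate,
                    effect=EffectProfile("lag", c, DESIGN_LOG_HR),
                    n_subjects=n_subjects,
                    scenario_id=f"lag_{rate.label}_t{c:g}",
                )
            )
    for rate in CANONICAL_RATES:
        for c in EARLY_TIMES:
            grid.append(
                ScenarioSpec(
                    rate=rate,
                    effect=EffectProfile("early", c, DESIGN_LOG_HR),
                    n_subjects=n_subjects,
                    scenario_id=f"early_{rate.label}_t{c:g}",
                )
            )
    for rate in CANONICAL_RATES:
        grid.append(
            ScenarioSpec(
                rate=rate,
                effect=EffectProfile("null", 0.0, 0.0),
                n_subjects=n_subjects,
                scenario_id=f"null_{rate.label}",
            )
        )
    return grid


def is_ph_cell(scenario: ScenarioSpec) -> bool:
    eff = scenario.effect
    if eff.kind == "ph":
        return True
    if eff.kind == "lag" and eff.change_time == 0.0:
        return True
    if eff.kind == "early" and eff.change_time >= scenario.horizon:
        return True
    return False


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

TRIAL_CSV_COLUMNS = ["subject_id", "arm", "time", "event", "scenario_id", "seed"]


def write_trials_csv(datasets: Iterable[TrialDataset], path) -> None:
    frames = [d.to_dataframe() for d in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> list[TrialDataset]:
    df = pd.read_csv(path)
    missing = {"arm", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    if "scenario_id" not in df.columns:
        return [TrialDataset.from_dataframe(df)]
    return [
        TrialDataset.from_dataframe(g.reset_index(drop=True))
        for _, g in df.groupby("scenario_id", sort=False)
    ]
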