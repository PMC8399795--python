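"""Study orchestration: scenario grid x methods x replicates.

Seeding discipline: replicate r of scenario s (s indexed in the full grid
order) draws from the substream SeedSequence([base_seed, s, r]), so the
simulated datasets are identical no matter which subset of scenarios or
methods is selected.  The combination test's permutation stream is the
further child SeedSequence([base_seed, s, r, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, rpmodel, survtests
from .performance import DesignBenchmark, design_benchmark, summarise_fits, summarise_tests
from .scenarios import ScenarioSpec, TrialDataset, sample_trial, scenario_grid

logger = logging.getLogger(__name__)

ALL_METHODS = ("cox", "lm", "pe1", "pe2", "weibull_aft", "rp_ph", "rp_td")

FIT_COLUMNS = [
    "scenario_id", "replicate", "method", "estimand", "point", "se",
    "ci_low", "ci_high", "p", "converged",
]
TEST_COLUMNS = ["scenario_id", "replicate", "test_name", "statistic", "p"]


@dataclass
class RunConfig:
    base_seed: int = 1
    n_sims: int = 2000
    scenarios: list[str] | None = None  # scenario_id filter
    methods: list[str] | None = None
    tests: list[str] | None = None
    n_subjects: int | None = None
    out_dir: str = "results/study"
    keep_replicates: bool = True
    n_permutations: int = 1000
    n_benchmark: int = 250_000

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        known = {s.scenario_id for s in scenario_grid()}
        for sid in self.scenarios or []:
            if sid not in known:
                raise ValueError(f"unknown scenario_id {sid!r}")
        for m in self.methods or []:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}")
        for t in self.tests or []:
            if t not in survtests.ALL_TESTS:
                raise ValueError(f"unknown test {t!r}")


_CONFIG_KEYS = {f.name for f in RunConfig.__dataclass_fields__.values()}


def load_config(path) -> RunConfig:
    """Read a key: value config file; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def replicate_seed(base_seed: int, scenario_index: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), int(scenario_index), int(replicate)])


def _landmark_time(scenario: ScenarioSpec) -> float:
    # pre-specified per non-PH form: 3 months for lag, 10 for early effect
    return 10.0 if scenario.effect.kind == "early" else 3.0


def fit_methods(
    data: TrialDataset, methods=ALL_METHODS, scenario: ScenarioSpec | None = None
) -> list[estimators.EstimateResult]:
    """Run the selected estimators on one trial."""
    scenario = scenario or data.scenario
    out: list[estimators.EstimateResult] = []
    for m in methods:
        if m == "cox":
            out.append(estimators.fit_cox(data))
        elif m == "lm":
            out.append(estimators.fit_cox(data, landmark_time=_landmark_time(scenario)))
        elif m == "pe1":
            out.append(estimators.fit_piecewise_exponential(data))
        elif m == "pe2":
            pre, post = estimators.fit_piecewise_exponential(data, period_specific_from=3.0)
            out.append(post)  # canonical PE2 summary: HR from events after t_PE
        elif m == "weibull_aft":
            out.append(estimators.fit_weibull(data, "aft"))
        elif m == "rp_ph":
            fit = rpmodel.fit_rp(data, baseline_df=5, td_df=0)
            out.append(rpmodel.rp_hr(fit))
            out.append(rpmodel.rmst_difference(fit))
        elif m == "rp_td":
            fit = rpmodel.fit_rp(data, baseline_df=5, td_df=2)
            out.append(rpmodel.rmst_difference(fit))
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def _select_scenarios(config: RunConfig):
    grid = scenario_grid(config.n_subjects) if config.n_subjects else scenario_grid()
    indexed = list(enumerate(grid))
    if config.scenarios:
        indexed = [(i, s) for i, s in indexed if s.scenario_id in config.scenarios]
    return indexed


def _run_cell(scenario, s_idx, config: RunConfig, methods, tests):
    fit_rows, test_rows = [], []
    estimates_by_key: dict = {}
    tests_by_key: dict = {}
    for r in range(config.n_sims):
        ss = replicate_seed(config.base_seed, s_idx, r)
        data = sample_trial(scenario, np.random.default_rng(ss))
        if methods:
            for est in fit_methods(data, methods, scenario):
                key = (scenario.scenario_id, est.method, est.estimand)
                estimates_by_key.setdefault(key, []).append(est)
                fit_rows.append(
                    (scenario.scenario_id, r, est.method, est.estimand, est.point,
                     est.se, est.ci_low, est.ci_high, est.p_value, est.converged)
                )
        if tests:
            trng = np.random.default_rng(
                np.random.SeedSequence([config.base_seed, s_idx, r, 1])
            )
            for tr in survtests.run_tests(
                data, tests, n_permutations=config.n_permutations, rng=trng
            ):
                tests_by_key.setdefault((scenario.scenario_id, tr.name), []).append(tr)
                test_rows.append((scenario.scenario_id, r, tr.name, tr.statistic, tr.p_value))
    return fit_rows, test_rows, estimates_by_key, tests_by_key


def run_study(
    config: RunConfig,
    benchmark: DesignBenchmark | None = None,
    force: bool = False,
) -> Path:
    """Full study loop: simulate -> fit -> test -> summarise, resumable per cell.

    Per-cell CSVs are written under out_dir/cells/; an existing complete cell
    is skipped (and reloaded for the summary) unless ``force`` is set.  Two
    runs with the same config produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    cells = out / "cells"
    cells.mkdir(parents=True, exist_ok=True)
    methods = tuple(config.methods) if config.methods is not None else ALL_METHODS
    tests = tuple(config.tests) if config.tests is not None else survtests.ALL_TESTS
    if benchmark is None:
        benchmark = design_benchmark(config.n_benchmark, seed=config.base_seed)

    all_fits, all_tests = [], []
    est_by_key: dict = {}
    tst_by_key: dict = {}
    for s_idx, scenario in _select_scenarios(config):
        sid = scenario.scenario_id
        fit_path = cells / f"{sid}_fits.csv"
        test_path = cells / f"{sid}_tests.csv"
        done = (not methods or fit_path.exists()) and (not tests or test_path.exists())
        if done and not force:
            logger.info("cell %s: resuming from existing output", sid)
            if methods:
                all_fits.append(pd.read_csv(fit_path))
            if tests:
                all_tests.append(pd.read_csv(test_path))
            continue
        # skip pe2 for early-effect scenarios (not part of the canonical tables)
        cell_methods = tuple(
            m for m in methods if not (m == "pe2" and scenario.effect.kind == "early")
        )
        frows, trows, ebk, tbk = _run_cell(scenario, s_idx, config, cell_methods, tests)
        est_by_key.update(ebk)
        tst_by_key.update(tbk)
        n_bad = sum(1 for es in ebk.values() for e in es if not e.converged)
        logger.info("cell %s: %d replicates, %d non-converged fits", sid, config.n_sims, n_bad)
        if methods:
            fdf = pd.DataFrame(frows, columns=FIT_COLUMNS)
            fdf.to_csv(fit_path, index=False)
            all_fits.append(fdf)
        if tests:
            tdf = pd.DataFrame(trows, columns=TEST_COLUMNS)
            tdf.to_csv(test_path, index=False)
            all_tests.append(tdf)

    if all_fits and config.keep_replicates:
        pd.concat(all_fits, ignore_index=True).to_csv(out / "fits.csv", index=False)
    if all_tests and config.keep_replicates:
        pd.concat(all_tests, ignore_index=True).to_csv(out / "tests.csv", index=False)
    if est_by_key:
        summarise_fits(est_by_key, benchmark).to_csv(out / "summary_fits.csv", index=False)
    elif all_fits:
        _summarise_from_frames(pd.concat(all_fits, ignore_index=True), benchmark).to_csv(
            out / "summary_fits.csv", index=False
        )
    if tst_by_key:
        summarise_tests(tst_by_key).to_csv(out / "summary_tests.csv", index=False)
    return out


def _summarise_from_frames(fits: pd.DataFrame, benchmark: DesignBenchmark) -> pd.DataFrame:
    """Rebuild the tidy summary from replicate-level CSV rows (resume path)."""
    by_key: dict = {}
    for row in fits.itertuples(index=False):
        est = estimators.EstimateResult(
            method=row.method, estimand=row.estimand, point=row.point, se=row.se,
            ci_low=row.ci_low, ci_high=row.ci_high, p_value=row.p,
            n_events_used=0, converged=bool(row.converged),
            log_point=np.log(row.point) if row.estimand in ("HR", "TR") and row.point > 0 else None,
        )
        by_key.setdefault((row.scenario_id, row.method, row.estimand), []).append(est)
    return summarise_fits(by_key, benchmark)


def run_type1_study(config: RunConfig, force: bool = False) -> Path:
    """Type I error study on the three null (beta = 0) scenarios.

    Runs every test plus the Cox z-test and reports rejection rates at
    alpha = 0.05 with their MCSEs.
    """
    null_ids = [s.scenario_id for s in scenario_grid() if s.effect.kind == "null"]
    sel = [sid for sid in (config.scenarios or null_ids) if sid in null_ids]
    cfg = RunConfig(
        base_seed=config.base_seed,
        n_sims=config.n_sims,
        scenarios=sel,
        methods=config.methods if config.methods is not None else [],
        tests=config.tests,
        n_subjects=config.n_subjects,
        out_dir=config.out_dir,
        keep_replicates=config.keep_replicates,
        n_permutations=config.n_permutations,
        n_benchmark=config.n_benchmark,
    )
    # benchmark is irrelevant for tests-only runs; avoid the large simulation
    bench = DesignBenchmark(drmst_design=1.0)
    return run_study(cfg, benchmark=bench, force=force)
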