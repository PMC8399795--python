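"""Performance of every estimator under the proportional-hazards design cell.

Runs the design cell (constant event rate, HR = exp(-0.4), 207 subjects,
administrative censoring at 50 months) and summarises power, scaled
treatment effect and coverage for the Cox, landmark, piecewise exponential,
Weibull AFT and flexible-parametric (spline) models.  Under PH every
approach should sit near the design values: 80% power, 100% STE, 95%
coverage.

Usage: python analysis/03_ph_design_cell.py [--seed 1] [--n-sims 500]
"""

import argparse
from pathlib import Path

from nphsim import RunConfig, run_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sims", type=int, default=500)
    ap.add_argument("--n-benchmark", type=int, default=250_000)
    ap.add_argument("--out", type=Path, default=Path("results/ph_design_cell"))
    ap.add_argument("--force", action="store_true")
    args = ap.parse_args()

    cfg = RunConfig(
        base_seed=args.seed,
        n_sims=args.n_sims,
        scenarios=["lag_constant_t0"],  # the PH design cell within the grid
        tests=["logrank", "versatile", "cox_z"],
        out_dir=str(args.out),
        n_benchmark=args.n_benchmark,
    )
    out = run_study(cfg, force=args.force)

    import pandas as pd

    fits = pd.read_csv(out / "summary_fits.csv")
    tests = pd.read_csv(out / "summary_tests.csv")
    cols = ["method", "estimand", "power_pct", "ste_pct", "coverage_pct", "mean_point"]
    print(fits[cols].round(1).to_string(index=False))
    print()
    print(tests[["test_name", "power_pct", "mcse_power"]].round(1).to_string(index=False))
    print(
        "\nReading: all summary estimands recover the design effect (STE ~100%) "
        "with near-nominal power and coverage when PH truly holds; the "
        "period-specific landmark fit pays a power price for discarding early events."
    )


if __name__ == "__main__":
    main()
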