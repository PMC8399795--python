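"""Event-timing structure of the lag-until-effect scenarios.

For each baseline-hazard shape and lag time, computes the expected fraction
of events falling in the no-effect period (closed form) and the simulated
mean of the per-trial pooled fraction.  These fractions explain the power
losses: the more events spent while HR = 1, the less information about the
treatment effect.

Usage: python analysis/02_event_timing.py [--seed 1] [--n-sims 2000]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nphsim import expected_event_fraction_before, sample_trial, scenario_grid
from nphsim.pipeline import replicate_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sims", type=int, default=2000)
    ap.add_argument("--out", type=Path, default=Path("results/event_timing.csv"))
    args = ap.parse_args()

    rows = []
    grid = scenario_grid()
    lag_cells = [s for s in grid if s.effect.kind == "lag" and s.effect.change_time > 0]
    for idx, scen in enumerate(lag_cells):
        c = scen.effect.change_time
        analytic = expected_event_fraction_before(scen)
        fracs = np.empty(args.n_sims)
        for r in range(args.n_sims):
            d = sample_trial(scen, np.random.default_rng(replicate_seed(args.seed, 200 + idx, r)))
            ev = d.event == 1
            fracs[r] = np.mean(d.time[ev] <= c)
        rows.append(
            {
                "scenario_id": scen.scenario_id,
                "rate": scen.rate.label,
                "t_lag": c,
                "analytic_pct": 100 * analytic,
                "simulated_pct": 100 * fracs.mean(),
                "mcse_pct": 100 * fracs.std(ddof=1) / np.sqrt(args.n_sims),
            }
        )
        print(
            f"{scen.scenario_id:22s} analytic {100*analytic:5.1f}%  "
            f"simulated {100*fracs.mean():5.1f}%  (MCSE {100*fracs.std(ddof=1)/np.sqrt(args.n_sims):.2f}%)"
        )

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"wrote {args.out}")
    print(
        "Reading: under a decreasing event rate the no-effect period absorbs the "
        "largest share of events, so lag scenarios lose the most power there."
    )


if __name__ == "__main__":
    main()
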