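"""Power, STE and coverage across the non-proportional-hazards grid.

Sweeps the lag-until-effect and early-effect-ceasing scenarios under all
three baseline-hazard shapes, summarising each method and test per cell.
This is the full factorial study behind the headline conclusions: power
falls with longer lags (or shorter effective periods), and the direction of
the baseline-hazard shape decides whether those losses are amplified
(decreasing rate under a lag) or softened (increasing rate under a lag; the
ordering flips for early effects).

At the published scale this is 24 cells x 2000 replicates; the default here
is 200 replicates per cell, enough to see every ordering.  An optional
figure plots power against the change time per method.

Usage: python analysis/05_power_surface.py [--seed 1] [--n-sims 200] [--plot]
"""

import argparse
from pathlib import Path

import pandas as pd

from nphsim import RunConfig, run_study, scenario_grid


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sims", type=int, default=200)
    ap.add_argument("--n-benchmark", type=int, default=250_000)
    ap.add_argument("--out", type=Path, default=Path("results/power_surface"))
    ap.add_argument("--plot", action="store_true")
    ap.add_argument("--force", action="store_true")
    args = ap.parse_args()

    effect_cells = [s.scenario_id for s in scenario_grid() if s.effect.kind in ("lag", "early")]
    cfg = RunConfig(
        base_seed=args.seed,
        n_sims=args.n_sims,
        scenarios=effect_cells,
        tests=["logrank", "fh_1_0", "fh_1_1", "fh_0_1", "versatile", "cox_z"],
        out_dir=str(args.out),
        n_benchmark=args.n_benchmark,
        n_permutations=500,
    )
    out = run_study(cfg, force=args.force)

    fits = pd.read_csv(out / "summary_fits.csv")
    tests = pd.read_csv(out / "summary_tests.csv")
    meta = fits["scenario_id"].str.extract(r"(?P<form>lag|early)_(?P<rate>\w+)_t(?P<t>[\d.]+)")
    fits = pd.concat([fits, meta], axis=1)
    fits["t"] = fits["t"].astype(float)

    for form in ("lag", "early"):
        sub = fits[(fits["form"] == form) & (fits["method"] == "cox")]
        pivot = sub.pivot_table(index="t", columns="rate", values="power_pct")
        print(f"\nCox power (%) under the {form} non-PH form, by event rate:")
        print(pivot.round(1).to_string())
    print(
        "\nReading: power declines monotonically as the no-effect window grows; at "
        "a 3-month lag an increasing event rate preserves the most power and a "
        "decreasing rate the least, and the ordering reverses for early effects."
    )

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, form in zip(axes, ("lag", "early")):
            sub = fits[(fits["form"] == form) & (fits["method"] == "cox")]
            for rate, g in sub.groupby("rate"):
                g = g.sort_values("t")
                ax.plot(g["t"], g["power_pct"], marker="o", label=rate)
            ax.set_xlabel("change time (months)")
            ax.set_title(f"{form} non-PH, Cox model")
        axes[0].set_ylabel("power (%)")
        axes[0].legend(title="event rate")
        fig.tight_layout()
        fig.savefig(out / "power_vs_change_time.png", dpi=150)
        print(f"wrote {out / 'power_vs_change_time.png'}")

    print(f"summaries in {out}")


if __name__ == "__main__":
    main()
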