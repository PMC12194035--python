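#!/usr/bin/env python
"""Visual predictive check and goodness of fit for the selected models.

Loads the first-line fitted model from step 03, simulates 300 replicate
datasets at the observed design, and reports the fraction of observed
survival fractions inside the simulated 10-90% band, plus observed-vs-
predicted summary statistics.  Writes the VPC table and an SVG overlay.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ttemeta import io
from ttemeta.inference import fit, observations_from_curve
from ttemeta.simulate import gof, vpc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", type=Path, default=ROOT / "results" / "fixtures")
    ap.add_argument("--fits", type=Path, default=ROOT / "results" / "fits")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "diagnostics")
    ap.add_argument("--seed", type=int, default=20240301)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((args.fixtures / "manifest.json").read_text())

    arms = [n for n, m in manifest["arms"].items() if m["line"] == "first"]
    frames = []
    for name in arms:
        curve = io.read_curve_csv(
            args.fixtures / f"curve_{name}.csv", args.fixtures / f"risk_{name}.csv",
            total_n=manifest["arms"][name]["n"], study_id=name,
        )
        frames.append(observations_from_curve(curve))
    data = pd.concat(frames, ignore_index=True)
    cov = pd.DataFrame({"race_nonasian": {"flaura_like": 0.38, "flaura_asia_like": 0.0}})

    selection = pd.read_csv(args.fits / "model_selection_first.csv")
    family = selection.loc[selection["selected"], "family"].iloc[0]
    fr = fit(family, data, cov)

    rep = vpc(fr, data, cov, n_sim=300, seed=args.seed)
    rep.table.to_csv(args.out / "vpc_table.csv", index=False)
    table, summary = gof(fr, data, cov)
    table.to_csv(args.out / "gof_table.csv", index=False)
    (args.out / "summary.json").write_text(json.dumps(
        {"family": str(family), "fraction_in_band": rep.fraction_in_band, **summary},
        indent=1,
    ))
    print(f"selected family: {family}")
    print(f"VPC: {100 * rep.fraction_in_band:.1f}% of observations inside the 10-90% band")
    print(f"GOF: R^2={summary['r2']:.4f}, max |residual|={summary['max_abs_residual']:.4f}")

    _plot(rep, args.out / "vpc.svg")


def _plot(rep, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid, sub in rep.table.groupby("study_id"):
        sub = sub.sort_values("time")
        ax.fill_between(sub["time"], sub["sim_p10"], sub["sim_p90"], alpha=0.25)
        ax.plot(sub["time"], sub["sim_p50"], lw=1)
        ax.plot(sub["time"], sub["obs"], "o", ms=3, label=sid)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival fraction")
    ax.legend(fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


if __name__ == "__main__":
    main()
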