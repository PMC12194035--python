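#!/usr/bin/env python
"""Generate the synthetic trial-arm fixtures the rest of the analysis uses.

The original inputs of this analysis are survival curves digitized from
published trial figures, which cannot be redistributed.  This step generates
four synthetic arms with the same design (two first-line arms, n=279 with a
62/38 Asian/non-Asian mix and n=71 all-Asian; two second-line arms, n=129
and n=279) from the published final-model parameters, digitizes each onto a
40-point grid with a 6-month risk table, and writes the curve/risk/IPD CSVs.
"""

import argparse
import json
from pathlib import Path

from ttemeta import io
from ttemeta.synthetic import make_benchmark_suite

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240301)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "fixtures")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    bundle = make_benchmark_suite(args.seed)
    manifest = {"seed": args.seed, "arms": {}}
    for name, arm in bundle["arms"].items():
        io.write_ipd_csv(arm["ipd"], args.out / f"ipd_{name}.csv")
        io.write_curve_csv(
            arm["curve"], args.out / f"curve_{name}.csv", args.out / f"risk_{name}.csv"
        )
        manifest["arms"][name] = {
            "line": arm["line"],
            "n": arm["n"],
            "events": int(arm["ipd"]["event"].sum()),
        }
        print(f"{name}: n={arm['n']} events={manifest['arms'][name]['events']} "
              f"({arm['line']}-line)")
    io.write_ipd_csv(bundle["recovery_ipd"], args.out / "ipd_recovery.csv")
    (args.out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"fixtures written to {args.out}")


if __name__ == "__main__":
    main()
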