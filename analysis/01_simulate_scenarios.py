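#!/usr/bin/env python
"""Generate one example dataset per pleiotropy scenario.

Writes summary-statistic TSVs plus ground-truth JSON for the vertical,
horizontal (directional and balanced), InSIDE-violation, confounding
triangle, and bidirectional designs under ``results/fixtures/``.  These
files are regenerable byte-for-byte from the seeds printed below.
"""

import argparse
from pathlib import Path

from pleiomr.synthetic_data import (ScenarioConfig, simulate_bidirectional,
                                    simulate_pair, simulate_triangle,
                                    write_fixture)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2020)
    ap.add_argument("--out-dir", type=Path, default=Path("results/fixtures"))
    args = ap.parse_args()

    pair_scenarios = ("V", "H-directional", "H-balanced",
                      "C-inside-violation")
    for i, scenario in enumerate(pair_scenarios):
        cfg = ScenarioConfig(scenario=scenario, seed=args.seed + i,
                             flip_fraction=0.3)
        exp, out, truth = simulate_pair(cfg)
        d = args.out_dir / scenario
        write_fixture([exp, out], truth, d)
        print(f"{scenario:20s} seed={cfg.seed}  k={cfg.k}  -> {d}")

    cfg = ScenarioConfig(scenario="TRIANGLE", theta=(0.0, 0.4, 0.5),
                         seed=args.seed + 10, flip_fraction=0.3)
    edu, conf, out, truth = simulate_triangle(cfg)
    write_fixture([edu, conf, out], truth, args.out_dir / "TRIANGLE")
    print(f"{'TRIANGLE':20s} seed={cfg.seed}  arrows={cfg.theta}  "
          f"-> {args.out_dir / 'TRIANGLE'}")

    cfg = ScenarioConfig(seed=args.seed + 11, theta=(0.45, 0.3),
                         flip_fraction=0.3)
    ta, tb, truth = simulate_bidirectional(cfg)
    write_fixture([ta, tb], truth, args.out_dir / "BIDIRECTIONAL")
    print(f"{'BIDIRECTIONAL':20s} seed={cfg.seed}  theta={cfg.theta}  "
          f"shared-significant SNPs: "
          f"{len(truth.extras['significant_both'])}")


if __name__ == "__main__":
    main()
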