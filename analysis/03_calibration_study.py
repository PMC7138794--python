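#!/usr/bin/env python
"""Replicate studies: estimator calibration and robustness.

500 seeded replicates per scenario.  Under vertical pleiotropy the IVW mean
should sit within 0.02 of the true effect with ~95% CI coverage and a
controlled Egger-intercept test; under directional pleiotropy (40% invalid
SNPs) the IVW acquires a positive bias that the weighted median largely
avoids, while the intercept test gains power.
"""

import argparse
from pathlib import Path

import pandas as pd

from pleiomr import montecarlo


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--reps", type=int, default=500)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    v = montecarlo.vertical_calibration(n_reps=args.reps, seed=args.seed)
    print("vertical pleiotropy (valid instruments, theta = "
          f"{v['theta']}):")
    print(f"  mean IVW beta      {v['mean_ivw_beta']:+.4f}")
    print(f"  95% CI coverage    {v['ci_coverage']:.3f}")
    print(f"  Egger-int. type I  {v['egger_intercept_rejection_rate']:.3f}")

    h = montecarlo.directional_robustness(n_reps=args.reps,
                                          seed=args.seed + 1)
    print("directional horizontal pleiotropy (40% invalid SNPs):")
    print(f"  IVW mean bias          {h['ivw_mean_bias']:+.4f}")
    print(f"  weighted-median bias   {h['weighted_median_mean_bias']:+.4f}")
    print(f"  Egger-intercept power  {h['egger_intercept_rejection_rate']:.3f}")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"study": "vertical", **v}, {"study": "directional", **h}]
    pd.DataFrame(rows).to_csv(args.out_dir / "calibration_summary.tsv",
                              sep="\t", index=False, float_format="%.6g")
    print(f"wrote {args.out_dir / 'calibration_summary.tsv'}")


if __name__ == "__main__":
    main()
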