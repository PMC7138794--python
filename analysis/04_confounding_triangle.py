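#!/usr/bin/env python
"""Univariable vs multivariable MR in the confounding triangle.

A bipolar-like confounder drives both an education-like exposure
(delta1 = 0.4) and a schizophrenia-like outcome (delta2 = 0.5) while the
exposure's true direct effect is 0.  The univariable analysis of the
exposure picks up confounder-driven instruments and reports a spurious
positive effect; adjusting for the confounder in a multivariable model
returns the direct effect to the null — the qualitative reversal the
multivariable design exists to detect.  Runs one full pipeline example plus
a 500-replicate study.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from pleiomr import montecarlo
from pleiomr.pipeline import (AnalysisPlan, MrOptions, comparison_table,
                              run_plan)
from pleiomr.synthetic_data import ScenarioConfig, simulate_triangle


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=23)
    ap.add_argument("--reps", type=int, default=500)
    ap.add_argument("--out-dir", type=Path, default=Path("results/triangle"))
    args = ap.parse_args()

    cfg = ScenarioConfig(scenario="TRIANGLE", theta=(0.0, 0.4, 0.5),
                         seed=args.seed, flip_fraction=0.3)
    edu, conf, out, _ = simulate_triangle(cfg)
    plan = AnalysisPlan(
        tables={"education": edu, "bipolar": conf, "schizophrenia": out},
        tests=[
            {"id": "uni_education", "type": "univariable",
             "exposure": "education", "outcome": "schizophrenia"},
            {"id": "uni_bipolar", "type": "univariable",
             "exposure": "bipolar", "outcome": "schizophrenia"},
            {"id": "mv_education_bipolar", "type": "multivariable",
             "exposures": ["education", "bipolar"],
             "outcome": "schizophrenia"},
        ],
        options=replace(MrOptions(seed=args.seed), remove_outliers=False))
    reports = run_plan(plan, args.out_dir)
    cmp = comparison_table(reports)
    print("single-dataset comparison (total vs direct):")
    print(cmp[["exposure", "total_beta", "direct_beta",
               "direct_pval"]].to_string(index=False))

    study = montecarlo.triangle_reversal(n_reps=args.reps, seed=args.seed)
    print(f"\n{args.reps}-replicate study (true direct effect "
          f"{study['true_direct_effect']}):")
    print(f"  mean univariable beta    {study['univariable_mean_beta']:+.4f}")
    print(f"  mean multivariable beta  {study['multivariable_mean_beta']:+.4f}")
    print(f"  mean confounder beta     "
          f"{study['multivariable_confounder_mean_beta']:+.4f}")
    pd.DataFrame([study]).to_csv(args.out_dir / "reversal_study.tsv",
                                 sep="\t", index=False, float_format="%.6g")
    print(f"wrote {args.out_dir}")


if __name__ == "__main__":
    main()
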