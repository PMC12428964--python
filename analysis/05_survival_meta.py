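#!/usr/bin/env python
"""Survival meta-analysis: per-study Cox fits pooled across three cohorts.

Simulates the three-study design (n = 124, 95, 498) under a shared true
per-unit hazard ratio of 0.67 for the expression covariate, fits each
study with the package's Cox routine, pools the log hazard ratios under
the common-effect and DerSimonian-Laird random-effects models, and then
repeats the whole pipeline over 200 seeds to show the pooled estimate is
recovered on average.  Writes results/meta_analysis.csv.
"""

import argparse
import math
from pathlib import Path

import numpy as np
import pandas as pd

from neurogg.stats import cox_fit_single, meta_fixed_random
from neurogg.synthetic import SurvivalSimParams, simulate_survival_study

SIZES = (124, 95, 498)
TRUE_HR = 0.67


def one_replicate(rng):
    estimates, ses, per_study = [], [], []
    for n in SIZES:
        study = simulate_survival_study(SurvivalSimParams(n=n, hazard_ratio=TRUE_HR),
                                        rng=rng)
        fit = cox_fit_single(study["time"], study["event"], study["x"])
        estimates.append(fit.log_hr)
        ses.append(fit.se)
        per_study.append(fit)
    return meta_fixed_random(estimates, ses), per_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/meta_analysis.csv")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    meta, fits = one_replicate(rng)
    print("single replicate (the forest-plot view):")
    for n, fit in zip(SIZES, fits):
        lo, hi = fit.ci95
        print(f"  study n={n:3d}: HR={fit.hr:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
              f"events={fit.n_events}")
    print(f"  pooled common:  HR={math.exp(meta.common_effect):.3f} "
          f"(SE {meta.common_se:.3f})")
    print(f"  pooled random:  HR={math.exp(meta.random_effect):.3f} "
          f"(SE {meta.random_se:.3f})")
    print(f"  tau2={meta.tau2:.4f}  I2={100 * meta.i2:.1f}%  "
          f"Q({meta.df})={meta.q:.3f}  p_Q={meta.p_q:.3f}")

    pooled = [math.exp(one_replicate(rng)[0].common_effect) for _ in range(200)]
    print(f"\nrecovery over 200 replicates: mean pooled HR = {np.mean(pooled):.4f} "
          f"(true {TRUE_HR})")

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "pooled_hr_common": math.exp(meta.common_effect),
        "pooled_hr_random": math.exp(meta.random_effect),
        "tau2": meta.tau2, "i2_percent": 100 * meta.i2,
        "q": meta.q, "df": meta.df, "p_q": meta.p_q,
        "mean_pooled_hr_200_reps": float(np.mean(pooled)),
        "true_hr": TRUE_HR,
    }]).to_csv(out, index=False)
    print(f"-> {out}")


if __name__ == "__main__":
    main()
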