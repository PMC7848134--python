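#!/usr/bin/env python
"""Group contrasts of the winning model's parameters and correlations.

Mann-Whitney children-vs-adolescents comparisons of beta, omega and the
mean learning rate (across and within feedback conditions), reversal-
aligned learning-rate/value curves per group, and parameter-behaviour plus
parameter-rigidity correlations.
"""
import argparse
from pathlib import Path

import pandas as pd

import revlearn as rl


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
    ap.add_argument("--trajectories", type=Path,
                    default=Path("results/trajectories_hgf_fixed_theta.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = rl.read_cohort(args.cohort)
    fits = pd.read_csv(args.fits)
    groups = list(dict.fromkeys(cohort.subjects["group"]))

    params = rl.parameter_comparison(fits, "hgf_fixed_theta", groups)
    errors = rl.error_summary(cohort.trials)
    corrs = rl.correlation_report(fits, errors, cohort.subjects,
                                  "hgf_fixed_theta")

    traj = pd.read_csv(args.trajectories)
    trajectories = {(sid, cond, "hgf_fixed_theta"): t
                    for (sid, cond), t in traj.groupby(
                        ["subject_id", "condition"])}
    aligned = rl.aligned_trajectories(cohort.trials, trajectories,
                                      "hgf_fixed_theta")

    args.out.mkdir(parents=True, exist_ok=True)
    params.to_csv(args.out / "param_comparison.csv", index=False)
    corrs.to_csv(args.out / "correlations.csv", index=False)
    aligned.to_csv(args.out / "aligned_trajectories.csv", index=False)

    print("parameter comparison (Mann-Whitney):")
    for _, r in params.iterrows():
        print(f"  {r['measure']:14s} [{r['condition']:10s}] U={r['U']:6.1f} "
              f"z={r['z']:6.2f} p={r['p']:.3f}")
    print("\ncorrelations:")
    for _, r in corrs.iterrows():
        print(f"  {r['x']:6s} ~ {r['y']:18s} r={r['r']:6.3f} p={r['p']:.3f}")


if __name__ == "__main__":
    main()
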