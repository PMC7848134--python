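#!/usr/bin/env python
"""Error taxonomy and mixed ANOVAs on the cohort's trial logs.

Classifies every run's errors into perseverative / regressive /
first-block-unclassified, summarises percentages per group and condition,
and runs the 3 (feedback condition) x 2 (age group) mixed ANOVA for each
error measure.
"""
import argparse
from pathlib import Path

import revlearn as rl


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = rl.read_cohort(args.cohort)
    errors = rl.error_summary(cohort.trials)
    anovas = rl.error_anovas(errors)
    args.out.mkdir(parents=True, exist_ok=True)
    errors.to_csv(args.out / "errors.csv", index=False)
    anovas.to_csv(args.out / "error_anovas.csv", index=False)

    print("mean error percentages (by group):")
    print(errors.groupby("group")[["overall_pct", "perseverative_pct",
                                   "regressive_pct"]].mean().round(2))
    print("\nmixed condition x group ANOVAs:")
    for _, row in anovas.iterrows():
        print(f"  {row['measure']:18s} {row['effect']:12s} "
              f"F({row['df1']:.0f},{row['df2']:.0f})={row['F']:.2f}  "
              f"p={row['p']:.3f}")


if __name__ == "__main__":
    main()
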