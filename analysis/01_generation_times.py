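#!/usr/bin/env python
"""Generation times of the three focal strains and their pairwise contrasts.

Generates triplicate plate-reader growth curves at each strain's measured
anaerobic doubling time (1% multiplicative noise), re-estimates the doubling
times by mid-log window regression, and tests the printed summary contrasts:
the gleaner strain EDM106 grows significantly more slowly anaerobically than
both EDM116 and EDM530.

Writes results/generation_times.csv and results/generation_time_tests.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from shulk.kinetics import generation_time_replicates
from shulk.stats import GroupSummary, t_test_summary
from shulk.synth import gen_growth_curves

# Printed anaerobic and aerobic summaries: (mean doubling min, se, n).
ANAEROBIC = {"EDM106": (56.50, 0.30, 3), "EDM116": (50.97, 0.32, 3),
             "EDM530": (49.03, 0.24, 3)}
AEROBIC = {"EDM106": (38.12, 0.35, 3), "EDM116": (40.98, 0.49, 3),
           "EDM530": (41.56, 0.72, 3)}


def main(seed: int, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for condition, table in (("anaerobic", ANAEROBIC), ("aerobic", AEROBIC)):
        for i, (strain, (td, se, n)) in enumerate(table.items()):
            cs = gen_growth_curves(doubling_min=td, noise_sd=0.01,
                                   seed=seed + 10 * i + (condition == "aerobic"),
                                   condition=condition)
            mean, se_hat, fits = generation_time_replicates(cs.curves)
            rows.append({"strain": strain, "condition": condition,
                         "doubling_min_reference": td,
                         "doubling_min_estimated": round(mean, 2),
                         "se_estimated": round(se_hat, 3),
                         "n_replicates": len(fits)})
    est = pd.DataFrame(rows)
    est.to_csv(out_dir / "generation_times.csv", index=False)
    print(est.to_string(index=False))

    tests = []
    for condition, table in (("anaerobic", ANAEROBIC), ("aerobic", AEROBIC)):
        a = GroupSummary(*table["EDM106"])
        for other in ("EDM116", "EDM530"):
            res = t_test_summary(a, GroupSummary(*table[other]),
                                 variant="welch", tails=2)
            tests.append({"condition": condition,
                          "contrast": f"EDM106 vs {other}",
                          "t": round(res.statistic, 3),
                          "df": round(res.df, 2),
                          "p": float(f"{res.p_value:.3g}")})
    tdf = pd.DataFrame(tests)
    tdf.to_csv(out_dir / "generation_time_tests.csv", index=False)
    print()
    print(tdf.to_string(index=False))
    print("\nEDM106 is the slowest strain anaerobically (both p < 0.01) yet "
          "the fastest aerobically — the early-colonizer profile.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out_dir)
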