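#!/usr/bin/env python
"""Electropherogram unmixing: the 84/16 worked case and the detection floor.

Generates pure-strain unit spectra and a mixed trace at the worked 84%/16%
two-strain composition (1% additive noise), decomposes it by constrained
multiple linear regression, and profiles recovery error as the true minor
fraction approaches the ~5% detection limit of the trace method.

Writes results/unmix_worked.json and results/detection_profile.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from shulk.synth import gen_traces
from shulk.unmix import unmix


def main(seed: int, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    tm, _ = gen_traces(mixture=(0.84, 0.16), noise_sd=0.01, seed=seed + 11)
    res = unmix(tm)
    payload = {
        "proportions_pct": {lab: round(float(100 * p), 2)
                            for lab, p in zip(res.labels, res.proportions)},
        "r_squared": round(res.r_squared, 4),
        "p_value": float(f"{res.p_value:.3g}"),
        "below_detection": dict(zip(res.labels,
                                    map(bool, res.below_detection))),
    }
    (out_dir / "unmix_worked.json").write_text(
        json.dumps(payload, indent=2) + "\n")
    print("Worked two-strain decomposition (true 84%/16%, 1% noise):")
    print(f"  recovered {payload['proportions_pct']}, "
          f"R^2 = {payload['r_squared']}, p = {payload['p_value']}")

    rows = []
    for minor in (0.02, 0.05, 0.10, 0.16, 0.30):
        errs = []
        for k in range(50):
            tm, _ = gen_traces(mixture=(1 - minor, minor), noise_sd=0.01,
                               seed=seed + 1000 * int(minor * 100) + k)
            r = unmix(tm)
            errs.append(abs(r.proportions[1] - minor))
        rows.append({"true_minor_fraction": minor,
                     "median_abs_error": float(f"{np.median(errs):.3g}"),
                     "flagged_below_detection": minor < 0.05})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "detection_profile.csv", index=False)
    print("\nRecovery of the minor component vs its true fraction:")
    print(df.to_string(index=False))
    print("\nComponents under ~5% sit at the reporting floor: they are "
          "flagged, not zeroed, mirroring how the trace method cannot "
          "certify exclusion below that level.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out_dir)
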