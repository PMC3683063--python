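#!/usr/bin/env python
"""Pair-alone serial-transfer competitions and the stationary-phase reversal.

Runs the calibrated gleaner/exploiter pair through serial batch culture at
transfer periods of 0.5-4 days (exploiter always wins, but more slowly the
longer the starvation tail of each cycle) and through a 16-day un-renewed
stationary culture (the gleaner eventually overtakes).

Writes results/transfer_period_sweep.csv and results/stationary_series.csv.
"""

import argparse
from pathlib import Path

from shulk import scenarios as sc
from shulk.io import write_series_csv


def main(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sweep = sc.run_transfer_period_sweep()
    sweep.to_csv(out_dir / "transfer_period_sweep.csv", index=False)
    print("Transfers until the gleaner drops below the 5% detection limit:")
    print(sweep.to_string(index=False))
    print("\nExclusion always happens, but takes more transfers the longer "
          "each cycle's low-nutrient phase — the sHULK signature.")

    stat = sc.run_stationary_phase(duration_days=16.0)
    write_series_csv(out_dir / "stationary_series.csv", stat.strain_series)
    final = stat.strain_series.fractions.iloc[-1]
    print(f"\nUn-renewed 16-day culture: final fractions "
          f"{sc.GLEANER}={final[sc.GLEANER]:.3f}, "
          f"{sc.EXPLOITER}={final[sc.EXPLOITER]:.3f} — "
          "the gleaner overtakes once the culture lives at the low "
          "quasi-steady peptone level sustained by biomass turnover.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    main(ap.parse_args().out_dir)
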