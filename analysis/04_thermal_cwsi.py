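#!/usr/bin/env python
"""Macro scale, thermal part: Crop Water Stress Index per plot and date.

CWSI = ((Tc - Ta) - LL)/(UL - LL) with the empirical lower/upper baselines
LL = a + b*VPD and UL = a + b*VPG, using the flight-time meteorology and the
mean canopy temperature over pure vegetation pixels.

Run: python analysis/04_thermal_cwsi.py [--seed N] [--fit-baseline]
"""

import argparse
from pathlib import Path

from fieldscale.io import PipelineConfig, write_table
from fieldscale.pipeline import process_spectral_thermal
from fieldscale.synthetic import SimConfig, simulate_field


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/cwsi.csv")
    ap.add_argument("--fit-baseline", action="store_true",
                    help="fit (a, b) by OLS on the 100%% PAW plots instead "
                         "of using the configured coefficients")
    args = ap.parse_args()

    dataset = simulate_field(SimConfig(seed=args.seed))
    config = PipelineConfig(seed=args.seed,
                            fit_baseline_from_reference=args.fit_baseline)
    _, cwsi_table, _, baseline = process_spectral_thermal(dataset, config)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    write_table(cwsi_table, args.out)

    mode = "fitted from 100% PAW plots" if args.fit_baseline else "configured"
    print(f"{len(cwsi_table)} records -> {args.out}")
    print(f"baseline ({mode}): Tc-Ta = {baseline.a:.2f} "
          f"{baseline.b:+.2f} * VPD  [degC, degC/kPa]")
    tbl = cwsi_table.assign(
        treatment=cwsi_table["plot_id"].map(dataset.treatment_of))
    print("mean CWSI per treatment and date:")
    print(tbl.pivot_table(index="dat", columns="treatment", values="cwsi")
          .round(2).to_string())


if __name__ == "__main__":
    main()
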