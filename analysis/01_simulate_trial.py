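#!/usr/bin/env python
"""Generate the synthetic drought trial used by every downstream analysis.

Three irrigation treatments (100/80/40% PAW) x 3 plots, imaged at nine DATs
(43-89), with continuous bioristor monitoring over DAT 30-90.  The deficit
treatment's stress severity ramps from DAT 65, mirroring the reported onset
of treatment separation.  Binary outputs (rasters, photos, traces) go to
scratch/dataset; the quick-look summary prints here.

Run: python analysis/01_simulate_trial.py [--seed N]
"""

import argparse

from fieldscale.io import write_dataset
from fieldscale.synthetic import SimConfig, simulate_field


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/dataset")
    args = ap.parse_args()

    config = SimConfig(seed=args.seed)
    dataset = simulate_field(config)
    write_dataset(dataset, args.out)

    print(f"trial written to {args.out} (seed={args.seed})")
    print(f"  plots: {len(dataset.plots)} "
          f"({config.plots_per_treatment} per treatment {config.treatments})")
    print(f"  imaging dates (DAT): {config.dates}")
    print(f"  bioristor traces: {len(dataset.traces)} "
          f"(window DAT {config.trace_start_dat}-"
          f"{config.trace_start_dat + config.trace_days}, "
          f"{config.sampling_interval_min}-min sampling)")
    late = config.dates[-1]
    for trt in config.treatments:
        s = dataset.truth.stress_severity[(f"T{trt}_P1", late)]
        g = dataset.truth.green_fraction[(f"T{trt}_P1", late)]
        print(f"  {trt:>3}% PAW at DAT {late}: severity {s:.2f}, "
              f"green fraction {g:.2f}")


if __name__ == "__main__":
    main()
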