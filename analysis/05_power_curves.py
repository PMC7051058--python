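#!/usr/bin/env python
"""Empirical power for the age-by-genotype interaction at the discovery
sample size (n = 783, MAF 0.49, alpha = 5e-8) over the interaction grid
betaI = -1.00 ... -0.75 in steps of 0.05.

Uses 2,000 Monte-Carlo replicates per grid point (the full calculation
uses 10,000; the reduced count keeps this driver interactive while the
Monte-Carlo SE stays ~0.01).  Writes results/power/power_grid.tsv."""

from pathlib import Path

from icsgwis import io as iomod
from icsgwis.power import PowerParams, power_grid

OUT = Path("results/power")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = PowerParams(alpha=5e-8, n_reps=2000, seed=20260922)
    tbl = power_grid(params)
    iomod.write_table(tbl, OUT / "power_grid.tsv")
    print("empirical power at n = 783, alpha = 5e-8 (2,000 replicates):")
    for _, row in tbl.iterrows():
        print(f"  betaI = {row.betaI:+.2f}: power {row.power:.3f} "
              f"(MC SE {row.mc_se:.3f}, {int(row.n_failed_fits)} failed fits)")


if __name__ == "__main__":
    main()
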