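#!/usr/bin/env python
"""Variant QC on the simulated cohorts: exclude variants with MAF < 1%,
call rate < 90%, HWE exact-test P < 1e-5 or INFO < 0.9 (strictly-below
semantics), and report per-rule exclusion counts.  Reads results/cohorts/,
writes results/qc/."""

from pathlib import Path

from icsgwis import io as iomod
from icsgwis.qc import apply_qc

IN, OUT = Path("results/cohorts"), Path("results/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for stage in ("discovery", "replication"):
        gm = iomod.read_vcf(IN / f"{stage}.vcf")
        kept, report = apply_qc(gm)
        iomod.write_table(report.flags, OUT / f"qc_report_{stage}.tsv")
        iomod.write_vcf(kept, OUT / f"{stage}.qcd.vcf")
        print(f"{stage}: {report.n_pass}/{report.n_input} variants pass QC; "
              f"exclusions by rule: {report.exclusions or 'none'}")


if __name__ == "__main__":
    main()
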