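#!/usr/bin/env python
"""Two-stage filtering and weighted Z-score joint analysis.

Variants must reach P < 1e-5 in discovery, P < 0.05 in replication, and
show direction-concordant interaction estimates; survivors are combined
with the sqrt(n)-weighted Z-score and flagged when the joint P clears
the genome-wide threshold 5e-8.  Writes results/joint/joint.tsv."""

from pathlib import Path

from icsgwis import io as iomod
from icsgwis.meta import run_two_stage

IN, OUT = Path("results/gwis"), Path("results/joint")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    disc = iomod.read_table(IN / "discovery.sumstats.tsv")
    rep = iomod.read_table(IN / "replication.sumstats.tsv")
    joint = run_two_stage(disc, rep)
    iomod.write_table(joint, OUT / "joint.tsv")
    print(f"{len(joint)} variant(s) pass both stage filters with concordant signs")
    for _, row in joint.iterrows():
        star = " (genome-wide significant)" if row["pass_joint"] else ""
        print(f"  {row['id']}: p_disc {row['p_disc']:.3g}, p_rep {row['p_rep']:.3g}"
              f" -> joint p {row['p_joint']:.3g}{star}")


if __name__ == "__main__":
    main()
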