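"""Candidate-gene proxy annotation.

Each candidate gene is represented by its top proxy variant: the
interaction-scan variant with the smallest P value lying within the gene
body extended by a flanking window (default 10 kb) on the same
chromosome.  Window bounds are inclusive on both sides in 1-based
coordinates; BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError


@dataclass
class GeneWindow:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    flank: int = 10_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidParameterError(f"{self.name}: start > end")
        if self.flank < 0:
            raise InvalidParameterError(f"{self.name}: flank must be >= 0")


def normalize_chrom(c) -> str:
    """'chr1' and '1' refer to the same chromosome."""
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def read_gene_windows(path, flank: int = 10_000, fmt: str | None = None) -> list[GeneWindow]:
    """Load gene windows from BED (0-based half-open) or TSV (1-based inclusive).

    Format is inferred from the extension unless ``fmt`` is given.  BED
    columns: chrom, start, end, name; TSV columns: name, chrom, start, end.
    """
    path = str(path)
    fmt = fmt or ("bed" if path.endswith(".bed") else "tsv")
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "gene"], usecols=range(4))
        return [GeneWindow(str(r.gene), str(r.chrom), int(r.start) + 1, int(r.end), flank)
                for r in df.itertuples(index=False)]
    df = pd.read_csv(path, sep="\t").rename(columns={"name": "gene"})
    return [GeneWindow(str(r.gene), str(r.chrom), int(r.start), int(r.end), flank)
            for r in df.itertuples(index=False)]


def assign_gene_proxy(results: pd.DataFrame, genes: list[GeneWindow]) -> pd.DataFrame:
    """Top proxy variant per gene window.

    ``results`` must carry chrom, pos, id and p columns.  Ties on P are
    broken by smaller position, then lexicographic id.  Genes with no
    in-window variant are reported with ``n_snps_in_window = 0`` and NaN
    proxy fields.
    """
    res = results.copy()
    res["_chrom"] = res["chrom"].map(normalize_chrom)
    rows = []
    for gw in genes:
        chrom = normalize_chrom(gw.chrom)
        lo, hi = gw.start - gw.flank, gw.end + gw.flank
        sub = res[(res["_chrom"] == chrom) & (res["pos"] >= lo) & (res["pos"] <= hi)]
        sub = sub[np.isfinite(sub["p"])]
        if len(sub) == 0:
            rows.append({"gene": gw.name, "proxy_id": None, "proxy_pos": np.nan,
                         "p": np.nan, "n_snps_in_window": 0})
            continue
        best = sub.sort_values(["p", "pos", "id"], kind="mergesort").iloc[0]
        rows.append({"gene": gw.name, "proxy_id": best["id"],
                     "proxy_pos": int(best["pos"]), "p": float(best["p"]),
                     "n_snps_in_window": int(len(sub))})
    return pd.DataFrame(rows, columns=["gene", "proxy_id", "proxy_pos", "p",
                                       "n_snps_in_window"])
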