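"""Small reference tables shipped with the package."""

from importlib import resources

import pandas as pd


def top_interactions() -> pd.DataFrame:
    """Published interaction odds ratios, 95% CIs and P values for the top 20
    replicated age-by-genotype interactions in the ICS-response GWIS.

    One interaction OR (95% CI) per stage plus the printed stage and
    joint P values.  Used to reconstruct stage Wald P values from the
    printed intervals (see :func:`icsgwis.gwis.wald_p_from_or_ci`).
    """
    with resources.files("icsgwis.data").joinpath("top_interactions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def candidate_genes() -> list[str]:
    """Default candidate-gene names for proxy annotation (coordinates are
    supplied by the user's BED/TSV; none are hard-coded)."""
    with resources.files("icsgwis.data").joinpath("candidate_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")["gene"].tolist()
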