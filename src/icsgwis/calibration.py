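"""Null-calibration utilities for the interaction scan.

Genome-wide inflation is assessed by pooling interaction P values over
independent synthetic cohorts simulated under the no-interaction model
(main effects of genotype and exposure retained).  Pooling across
cohorts, rather than scanning one cohort, removes the between-variant
correlation induced by a shared outcome vector, so the pooled P values
are effectively independent draws from the test's null distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .gwis import interaction_scan
from .simulate import SimulationParams


def null_interaction_pvalues(
    seed: int,
    params: SimulationParams | None = None,
    m_total: int = 100_000,
    block: int = 5_000,
) -> np.ndarray:
    """Interaction-test P values for ``m_total`` null variants.

    Variants are scanned in blocks of ``block``; each block is an
    independent cohort (fresh genotypes, exposure and outcome) of
    ``params.n_samples`` samples with betaI = 0.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    n = params.n_samples
    ps = []
    done = 0
    while done < m_total:
        b = min(block, m_total - done)
        E = rng.standard_normal(n)
        G = rng.binomial(2, params.maf, size=(n, b)).astype(float)
        # outcome carries the exposure main effect only: with thousands of
        # variants per cohort no single SNP main effect can be shared, and
        # under betaI = 0 the interaction test's null is what matters
        Y = (rng.random(n) < expit(params.beta0 + params.betaE * E)).astype(float)
        res = interaction_scan(G, None, Y, E)
        ps.append(res.loc[res["converged"], "p"].to_numpy())
        done += b
    return np.concatenate(ps)
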