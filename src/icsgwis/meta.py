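"""Two-stage discovery/replication filtering and weighted Z-score joint analysis.

A variant advances to joint analysis when its interaction P value is
genome-wide suggestive in discovery (P < 1e-5), nominally significant in
replication (P < 0.05), and the interaction effect has the same sign in
both stages.  Qualifying stage P values are combined with the
sample-size-weighted Z-score (Stouffer) statistic

    z_joint = sum_i w_i z_i / sqrt(sum_i w_i^2),   w_i = sqrt(n_i)

with z_i = sign_i * Phi^-1(1 - p_i/2), and the joint P reported
two-sided against the genome-wide threshold 5e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri_exp
from scipy.stats import norm

from .errors import InvalidParameterError

_P_FLOOR = 1e-300


@dataclass
class FilterCriteria:
    p_discovery_max: float = 1e-5
    p_replication_max: float = 0.05
    p_joint_max: float = 5e-8
    require_concordance: bool = True

    def __post_init__(self) -> None:
        for name in ("p_discovery_max", "p_replication_max", "p_joint_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1]; got {v}")


def signed_z_from_p(p_two_sided: float, direction: int) -> float:
    """Signed normal deviate from a two-sided P and an effect direction.

    Evaluated through the log-quantile function so that P values down to
    the smallest positive float convert without overflow.
    """
    if not 0.0 < p_two_sided <= 1.0:
        raise InvalidParameterError(f"p must lie in (0, 1]; got {p_two_sided}")
    if direction not in (-1, 1):
        raise InvalidParameterError(f"direction must be -1 or +1; got {direction}")
    # Phi^-1(p/2) via its logarithm: ndtri_exp(log p - log 2)
    z_mag = -ndtri_exp(np.log(p_two_sided) - np.log(2.0))
    return float(direction * z_mag)


def weighted_z_combine(stages: list[tuple[float, int, float]]) -> tuple[float, float]:
    """Stouffer sample-size-weighted combination.

    ``stages`` is a list of (p_two_sided, direction, n) triples; weights
    are sqrt(n).  Returns (z_joint, p_joint) with p_joint two-sided.
    """
    if not stages:
        raise InvalidParameterError("at least one stage required")
    zs, ws = [], []
    for p, d, n in stages:
        if n <= 0:
            raise InvalidParameterError(f"stage n must be positive; got {n}")
        zs.append(signed_z_from_p(p, d))
        ws.append(np.sqrt(n))
    zs_a, ws_a = np.asarray(zs), np.asarray(ws)
    z_joint = float(np.sum(ws_a * zs_a) / np.sqrt(np.sum(ws_a**2)))
    p_joint = float(max(2.0 * norm.sf(abs(z_joint)), _P_FLOOR))
    return z_joint, p_joint


def run_two_stage(
    disc: pd.DataFrame,
    rep: pd.DataFrame,
    criteria: FilterCriteria | None = None,
) -> pd.DataFrame:
    """Apply the stage filters and combine survivors with weighted Z.

    Both inputs are summary-statistics tables as produced by
    :func:`icsgwis.gwis.run_gwis` (columns id, beta_int, p, n, converged
    and optionally major/minor).  Non-converged rows never pass the
    filter.  Variants whose major/minor alleles disagree between stages
    are dropped with a log record in the ``dropped`` attribute of the
    returned frame (``.attrs['n_orientation_dropped']``).
    """
    criteria = criteria or FilterCriteria()
    merged = disc.merge(rep, on="id", suffixes=("_disc", "_rep"))
    n_dropped = 0
    if {"major_disc", "minor_disc", "major_rep", "minor_rep"} <= set(merged.columns):
        mismatch = (merged["major_disc"] != merged["major_rep"]) | (
            merged["minor_disc"] != merged["minor_rep"])
        n_dropped = int(mismatch.sum())
        merged = merged[~mismatch]

    ok = merged["converged_disc"].astype(bool) & merged["converged_rep"].astype(bool)
    merged = merged[ok]
    sign_disc = np.sign(merged["beta_int_disc"].to_numpy()).astype(int)
    sign_rep = np.sign(merged["beta_int_rep"].to_numpy()).astype(int)
    concordant = sign_disc == sign_rep
    keep = (
        (merged["p_disc"].to_numpy() < criteria.p_discovery_max)
        & (merged["p_rep"].to_numpy() < criteria.p_replication_max)
    )
    if criteria.require_concordance:
        keep &= concordant

    rows = []
    sel = merged[keep]
    for (_, row), sd, sr, conc in zip(
            sel.iterrows(), sign_disc[keep], sign_rep[keep], concordant[keep]):
        z, p = weighted_z_combine(
            [(row["p_disc"], int(sd) or 1, row["n_disc"]),
             (row["p_rep"], int(sr) or 1, row["n_rep"])])
        rows.append(
            {
                "id": row["id"],
                "p_disc": row["p_disc"],
                "p_rep": row["p_rep"],
                "sign_disc": int(sd),
                "sign_rep": int(sr),
                "concordant": bool(conc),
                "z_joint": z,
                "p_joint": p,
                "n_disc": int(row["n_disc"]),
                "n_rep": int(row["n_rep"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["id", "p_disc", "p_rep", "sign_disc", "sign_rep", "concordant",
                 "z_joint", "p_joint", "n_disc", "n_rep"],
    )
    if len(out):
        out["pass_joint"] = out["p_joint"] < criteria.p_joint_max
        out = out.sort_values("p_joint").reset_index(drop=True)
    else:
        out["pass_joint"] = pd.Series(dtype=bool)
    out.attrs["n_orientation_dropped"] = n_dropped
    return out
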