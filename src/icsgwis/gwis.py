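"""Per-variant logistic age-by-genotype interaction scan.

Each variant is tested in the model

    logit P(case) = b0 + bG*G + bE*E + bI*(G x E) + covariates

where G is the additive minor-allele dosage and E the rank-based
inverse-normal transform of age.  Inference on the interaction term is
a Wald test: z = bI / se(bI), p = 2*(1 - Phi(|z|)), with the 95%
confidence interval exp(bI +/- 1.96*se).  Fits are complete-case per
variant; quasi-separated or rank-deficient fits are retained in the
output but flagged ``converged = False`` and excluded from downstream
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .errors import (
    DegenerateOutcomeError,
    DimensionError,
    InvalidDataError,
    InvalidParameterError,
)
from .glm import fit_logistic_batch
from .simulate import GenotypeMatrix, SyntheticCohort

Z975 = norm.ppf(0.975)
CHI2_MEDIAN_1DF = chi2.ppf(0.5, df=1)  # 0.45494...
_P_FLOOR = 1e-300  # reported p values are clamped into (0, 1]


@dataclass
class InteractionModelSpec:
    """Model layout and IRLS controls for the interaction scan."""

    covariates: tuple[str, ...] = ("sex", "bmi", "study")
    n_pcs: int = 6
    max_iter: int = 50
    tol: float = 1e-10
    # interaction coefficient index within the core design [1, G, E, GxE, ...]
    idx_g: int = 1
    idx_e: int = 2
    idx_int: int = 3


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps value i to Phi^-1((r_i - 3/8) / (n + 1/4)) where r_i is the
    average rank.  Ties share the average rank, so an all-equal vector
    maps to zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise InvalidDataError("need a 1-D vector with at least one value")
    if not np.all(np.isfinite(v)):
        raise InvalidDataError("inverse-normal transform requires finite input")
    r = rankdata(v, method="average")
    return norm.ppf((r - 0.375) / (v.size + 0.25))


def encode_covariates(covariates: pd.DataFrame | None,
                      columns: tuple[str, ...] = ("sex", "bmi", "study"),
                      pcs: np.ndarray | None = None) -> np.ndarray:
    """Numeric design columns for the requested covariates.

    Categorical/object columns are one-hot encoded with the first level
    (sorted) as reference; numeric columns enter untransformed; optional
    PC scores are appended.
    """
    blocks: list[np.ndarray] = []
    if covariates is not None:
        for c in columns:
            if c not in covariates.columns:
                continue
            col = covariates[c]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(pd.unique(col.astype(str)))
                for lev in levels[1:]:
                    blocks.append((col.astype(str) == lev).to_numpy(dtype=float)[:, None])
            else:
                blocks.append(col.to_numpy(dtype=float)[:, None])
    if pcs is not None and pcs.size:
        blocks.append(np.asarray(pcs, dtype=float))
    if not blocks:
        return np.empty((len(covariates) if covariates is not None else 0, 0))
    return np.hstack(blocks)


@dataclass
class InteractionResult:
    variant_id: str
    beta_int: float
    se: float
    or_int: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    beta_g: float
    beta_e: float
    n_used: int
    converged: bool


def _wald(beta: float, se: float) -> tuple[float, float, float]:
    ci_low = float(np.exp(beta - Z975 * se))
    ci_high = float(np.exp(beta + Z975 * se))
    z = beta / se
    p = float(max(2.0 * norm.sf(abs(z)), _P_FLOOR))
    return ci_low, ci_high, p


def fit_interaction_model(
    outcome: np.ndarray,
    dosage: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    spec: InteractionModelSpec | None = None,
    variant_id: str = "variant",
) -> InteractionResult:
    """Single-variant maximum-likelihood logistic interaction fit.

    ``covariates`` is an already-encoded numeric matrix (see
    :func:`encode_covariates`) or None.  Missing values in any column
    drop the sample (complete-case).
    """
    spec = spec or InteractionModelSpec()
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(dosage, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if not (y.shape == g.shape == e.shape):
        raise DimensionError("outcome, dosage and exposure must have equal length")
    C = np.empty((y.size, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if C.shape[0] != y.size:
        raise DimensionError("covariate rows must match sample count")
    ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(e)
    if C.shape[1]:
        ok &= np.all(np.isfinite(C), axis=1)
    yy, gg, ee, CC = y[ok], g[ok], e[ok], C[ok]
    if yy.size == 0 or len(np.unique(yy)) < 2:
        raise DegenerateOutcomeError(f"{variant_id}: outcome has fewer than two classes")
    X = np.column_stack([np.ones_like(gg), gg, ee, gg * ee, CC])[None, :, :]
    res = fit_logistic_batch(X, yy[None, :], max_iter=spec.max_iter, tol=spec.tol)
    b = res.beta[0]
    se = res.se[0]
    conv = bool(res.converged[0])
    bi, si = float(b[spec.idx_int]), float(se[spec.idx_int])
    if conv and np.isfinite(si):
        ci_low, ci_high, p = _wald(bi, si)
    else:
        ci_low = ci_high = p = np.nan
        conv = False
    return InteractionResult(
        variant_id=variant_id,
        beta_int=bi,
        se=si,
        or_int=float(np.exp(bi)),
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=p,
        beta_g=float(b[spec.idx_g]),
        beta_e=float(b[spec.idx_e]),
        n_used=int(res.n_used[0]),
        converged=conv,
    )


def interaction_scan(
    dosages: np.ndarray,
    missing: np.ndarray | None,
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    spec: InteractionModelSpec | None = None,
    chunk_size: int = 2048,
) -> pd.DataFrame:
    """Vectorised interaction scan over a dosage matrix.

    Variants are stacked in batches and fitted simultaneously; missing
    dosage entries are handled per variant by zero observation weight
    (exactly equivalent to per-variant complete-case fitting).
    """
    spec = spec or InteractionModelSpec()
    D = np.asarray(dosages, dtype=float)
    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    n, m = D.shape
    if y.size != n or e.size != n:
        raise DimensionError("outcome/exposure length must match dosage rows")
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    base_ok = np.isfinite(y) & np.isfinite(e)
    if C.shape[1]:
        base_ok &= np.all(np.isfinite(C), axis=1)
    miss = np.zeros_like(D, dtype=bool) if missing is None else np.asarray(missing, dtype=bool)

    cols = {k: np.full(m, np.nan) for k in
            ("beta_int", "se", "or", "ci_low", "ci_high", "p", "beta_g", "beta_e")}
    n_used = np.zeros(m, dtype=int)
    converged = np.zeros(m, dtype=bool)

    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        Dc = D[:, lo:hi].T.copy()  # (B, n)
        Mc = miss[:, lo:hi].T | ~base_ok[None, :] | ~np.isfinite(Dc)
        Dc[Mc] = 0.0  # value irrelevant under zero weight
        B = hi - lo
        X = np.empty((B, n, 4 + C.shape[1]))
        X[:, :, 0] = 1.0
        X[:, :, 1] = Dc
        X[:, :, 2] = e[None, :]
        X[:, :, 3] = Dc * e[None, :]
        if C.shape[1]:
            X[:, :, 4:] = C[None, :, :]
        yb = np.where(Mc, 0.0, y[None, :])
        # degenerate outcomes (one class among complete cases) are flagged, not raised
        obs = ~Mc
        ones = (yb * obs).sum(axis=1)
        tot = obs.sum(axis=1)
        degenerate = (ones == 0) | (ones == tot) | (tot == 0)
        res = fit_logistic_batch(X, yb, mask=obs, max_iter=spec.max_iter, tol=spec.tol)
        conv = res.converged & ~degenerate
        b_int = res.beta[:, spec.idx_int]
        s_int = res.se[:, spec.idx_int]
        conv &= np.isfinite(s_int)
        sl = slice(lo, hi)
        cols["beta_int"][sl] = b_int
        cols["se"][sl] = s_int
        cols["or"][sl] = np.exp(b_int)
        cols["ci_low"][sl] = np.where(conv, np.exp(b_int - Z975 * s_int), np.nan)
        cols["ci_high"][sl] = np.where(conv, np.exp(b_int + Z975 * s_int), np.nan)
        with np.errstate(invalid="ignore"):
            p = 2.0 * norm.sf(np.abs(b_int / s_int))
        cols["p"][sl] = np.where(conv, np.maximum(p, _P_FLOOR), np.nan)
        cols["beta_g"][sl] = res.beta[:, spec.idx_g]
        cols["beta_e"][sl] = res.beta[:, spec.idx_e]
        n_used[sl] = res.n_used
        converged[sl] = conv

    out = pd.DataFrame(cols)
    out["n"] = n_used
    out["converged"] = converged
    return out


def run_gwis(
    cohort: SyntheticCohort | None = None,
    spec: InteractionModelSpec | None = None,
    *,
    genotypes: GenotypeMatrix | None = None,
    outcome: np.ndarray | None = None,
    exposure: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-variant interaction scan returning a summary-statistics table.

    Accepts either a :class:`SyntheticCohort` or the individual pieces.
    Output columns: chrom, pos, id, major, minor, maf, n, beta_g,
    beta_e, beta_int, se, or, ci_low, ci_high, p, converged.
    """
    spec = spec or InteractionModelSpec()
    if cohort is not None:
        genotypes = cohort.genotypes
        outcome = cohort.outcome
        exposure = cohort.exposure
        covariates = covariates if covariates is not None else cohort.covariates
    if genotypes is None or outcome is None or exposure is None:
        raise InvalidParameterError("need a cohort or genotypes+outcome+exposure")
    C = encode_covariates(covariates, spec.covariates, pcs=pcs)
    if C.shape[1] == 0:
        C = None
    scan = interaction_scan(
        genotypes.dosages, genotypes.missing, outcome, exposure, C, spec=spec)
    meta = genotypes.variants.reset_index(drop=True)
    dn = genotypes.dosages_with_nan()
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dn, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    out = pd.DataFrame(
        {
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "id": meta["id"].to_numpy(),
            "major": meta.get("major", pd.Series(["."] * len(meta))).to_numpy(),
            "minor": meta.get("minor", pd.Series(["."] * len(meta))).to_numpy(),
            "maf": maf,
        }
    )
    for c in ("n", "beta_g", "beta_e", "beta_int", "se", "or", "ci_low",
              "ci_high", "p", "converged"):
        out[c] = scan[c].to_numpy()
    return out


def wald_p_from_or_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Two-sided Wald P value reconstructed from a printed OR and 95% CI.

    se = (ln ci_high - ln ci_low) / (2 * 1.96); p = 2*(1 - Phi(|ln OR| / se)).
    """
    if not (0.0 < ci_low <= or_value <= ci_high):
        raise InvalidParameterError(
            f"need 0 < ci_low <= OR <= ci_high; got ({or_value}, {ci_low}, {ci_high})")
    if ci_low == ci_high:
        raise InvalidParameterError("degenerate CI (zero width)")
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z975)
    z = np.log(or_value) / se
    return float(max(2.0 * norm.sf(abs(z)), _P_FLOOR))


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 2 or np.any((p <= 0) | (p > 1)):
        raise InvalidParameterError("need >= 2 p values in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_MEDIAN_1DF)


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10(p) coordinates for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    exp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"expected_neglog10": -np.log10(exp),
                         "observed_neglog10": -np.log10(np.maximum(p, _P_FLOOR))})
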