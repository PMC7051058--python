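"""Pre-analysis variant filters and ancestry principal components.

Filters follow the conventional genome-wide defaults used by the study:
exclude variants with MAF < 1%, genotype call rate < 90%, imputation
INFO score < 0.9, or Hardy-Weinberg exact-test P < 1e-5.  Exclusion is
strictly-below in every rule: a variant exactly at a threshold passes.

The HWE exact test is the standard conditional enumeration: given the
observed allele counts, every heterozygote count of the right parity is
enumerated and the two-sided P value sums the probabilities of all
configurations no more likely than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import InvalidParameterError, UndefinedFrequencyError
from .simulate import GenotypeMatrix


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-5
    info_min: float = 0.9

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "info_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]; got {v}")


@dataclass
class QCReport:
    n_input: int
    n_pass: int
    exclusions: dict  # first-failing-rule -> count (sequential attribution)
    flags: pd.DataFrame = field(repr=False)  # per-variant metrics and failing rules

    def __post_init__(self) -> None:
        assert self.n_pass + sum(self.exclusions.values()) == self.n_input


def compute_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency from additive dosages; NaN marks missing."""
    d = np.asarray(dosages, dtype=float)
    called = d[~np.isnan(d)]
    if called.size == 0:
        raise UndefinedFrequencyError("no called genotypes; MAF undefined")
    f = called.mean() / 2.0
    return float(min(f, 1.0 - f))


def call_rate(dosages: np.ndarray) -> float:
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise InvalidParameterError("empty dosage vector")
    return float(np.mean(~np.isnan(d)))


def _hwe_log_weights(rare: int, common: int) -> tuple[np.ndarray, np.ndarray]:
    """Log relative weights over attainable het counts given allele counts."""
    hets = np.arange(rare % 2, rare + 1, 2)
    a = (rare - hets) // 2        # rare-allele homozygotes
    b = (common - hets) // 2      # common-allele homozygotes
    valid = b >= 0
    hets, a, b = hets[valid], a[valid], b[valid]
    n = (rare + common) // 2
    logw = (hets * np.log(2.0) + gammaln(n + 1)
            - gammaln(a + 1) - gammaln(hets + 1) - gammaln(b + 1))
    return hets, logw


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg P value from genotype counts.

    Computed in log space; ties on configuration probability are
    included with a 1e-9 relative tolerance.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise InvalidParameterError(f"genotype counts must be non-negative integers: {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise InvalidParameterError("at least one genotype required")
    ref = 2 * n_hom_ref + n_het
    alt = 2 * n_hom_alt + n_het
    rare, common = min(ref, alt), max(ref, alt)
    if rare == 0:
        return 1.0
    hets, logw = _hwe_log_weights(rare, common)
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[hets == n_het][0]
    p = w[w <= w_obs * (1.0 + 1e-9)].sum() / w.sum()
    return float(min(p, 1.0))


def hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest genotype in {0, 1, 2}; NaN preserved."""
    d = np.asarray(dosages, dtype=float)
    out = np.where(np.isnan(d), np.nan, np.clip(np.rint(d), 0, 2))
    return out


def hwe_p_from_dosages(dosages: np.ndarray) -> float:
    hc = hard_calls(dosages)
    hc = hc[~np.isnan(hc)]
    if hc.size == 0:
        return np.nan
    n0 = int(np.sum(hc == 0))
    n1 = int(np.sum(hc == 1))
    n2 = int(np.sum(hc == 2))
    return hwe_exact_test(n0, n1, n2)


# rule evaluation order fixes the sequential attribution in the report
_RULES = ("call_rate", "maf", "hwe", "info")


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    info_scores: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants on MAF, call rate, HWE and (when given) INFO score.

    ``info_scores`` defaults to the ``info_score`` column of the variant
    table when present; pass an array to override, or an all-NaN-free
    array of ones for typed (non-imputed) data.  A missing (NaN) score
    on an otherwise-checked variant is an exclusion ("info_missing").
    """
    thresholds = thresholds or QCThresholds()
    m = genotypes.n_variants
    if info_scores is None and "info_score" in genotypes.variants.columns:
        info_scores = genotypes.variants["info_score"].to_numpy(dtype=float)
    dn = genotypes.dosages_with_nan()

    mafs = np.full(m, np.nan)
    crs = np.zeros(m)
    hwes = np.full(m, np.nan)
    fail_rules: list[list[str]] = [[] for _ in range(m)]
    for j in range(m):
        col = dn[:, j]
        crs[j] = call_rate(col)
        if crs[j] < thresholds.call_rate_min:
            fail_rules[j].append("call_rate")
        if crs[j] > 0:
            mafs[j] = compute_maf(col)
            if mafs[j] < thresholds.maf_min:
                fail_rules[j].append("maf")
            hwes[j] = hwe_p_from_dosages(col)
            if hwes[j] < thresholds.hwe_p_min:
                fail_rules[j].append("hwe")
        else:
            # no calls at all: frequency undefined, attributed to call rate only
            pass
        if info_scores is not None:
            s = info_scores[j]
            if np.isnan(s):
                fail_rules[j].append("info_missing")
            elif s < thresholds.info_min:
                fail_rules[j].append("info")

    passed = np.array([not r for r in fail_rules])
    exclusions: dict[str, int] = {}
    for rules in fail_rules:
        if rules:
            first = rules[0]
            exclusions[first] = exclusions.get(first, 0) + 1
    flags = pd.DataFrame(
        {
            "id": genotypes.variants["id"].to_numpy(),
            "pass": passed,
            "fail_rules": [",".join(r) for r in fail_rules],
            "maf": mafs,
            "call_rate": crs,
            "hwe_p": hwes,
            "info_score": info_scores if info_scores is not None else np.nan,
        }
    )
    report = QCReport(n_input=m, n_pass=int(passed.sum()), exclusions=exclusions, flags=flags)
    return genotypes.subset_variants(np.flatnonzero(passed)), report


def pca_covariates(genotypes: GenotypeMatrix, k: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample principal-component scores from standardized genotypes.

    Missing entries are mean-imputed; each variant is centred at 2p and
    scaled by sqrt(2p(1-p)) before the SVD.  Returns ``(scores,
    explained_variance_ratio)`` with scores ordered by decreasing
    variance and mutually orthogonal columns.  If ``k`` exceeds the
    matrix rank, the attainable components are returned with a warning.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    dn = genotypes.dosages_with_nan()
    p_hat = np.nanmean(dn, axis=0) / 2.0
    filled = np.where(np.isnan(dn), 2.0 * p_hat[None, :], dn)
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = scale > 0
    Z = (filled[:, keep] - 2.0 * p_hat[None, keep]) / scale[None, keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    tol = S.max(initial=0.0) * max(Z.shape) * np.finfo(float).eps
    rank = int(np.sum(S > tol))
    if k > rank:
        warnings.warn(f"requested k={k} exceeds rank {rank}; returning {rank} components",
                      stacklevel=2)
        k = rank
    scores = U[:, :k] * S[:k]
    evr = (S**2 / np.sum(S**2))[:k]
    return scores, evr


def flag_pc_outliers(scores: np.ndarray, sd: float = 6.0) -> np.ndarray:
    """Samples beyond ±sd standard deviations on any component (ancestry flag)."""
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    return np.any(np.abs(z) > sd, axis=1)
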