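"""Batched maximum-likelihood logistic regression by Newton/IRLS.

This is the numerical core of the interaction scan and the power
simulator: many small logistic fits (one per variant, or one per
Monte-Carlo replicate) that share a common design structure.  Fits are
stacked along a leading batch axis and solved simultaneously with
batched normal equations, which is orders of magnitude faster than
looping over a general-purpose GLM fitter.

Conventions
-----------
* Design ``X`` has shape ``(B, n, p)`` (batch, samples, parameters).
* Observation weights/masks allow per-batch complete-case analysis:
  masked-out samples contribute neither to the score nor to the
  information matrix.
* Non-convergence and quasi-separation are reported per batch element,
  never raised: callers decide how to propagate the flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DimensionError

# Divergence guard: a logistic log-odds coefficient beyond this magnitude
# almost surely indicates (quasi-)separation rather than signal.
BETA_MAX = 15.0


@dataclass
class BatchGlmResult:
    """Estimates for a batch of logistic fits.

    Attributes
    ----------
    beta : (B, p) coefficient estimates.
    se : (B, p) Wald standard errors (NaN where not estimable).
    converged : (B,) True where the Newton iteration converged to an
        interior maximum with all ``|beta| <= BETA_MAX``.
    n_iter : iterations used (max over the batch).
    n_used : (B,) number of observations entering each fit.
    """

    beta: np.ndarray
    se: np.ndarray
    converged: np.ndarray
    n_iter: int
    n_used: np.ndarray


def _deviance(y: np.ndarray, mu: np.ndarray, mask: np.ndarray) -> np.ndarray:
    # Bernoulli deviance, summed per batch element over unmasked samples.
    eps = 1e-12
    ll = y * np.log(mu + eps) + (1.0 - y) * np.log(1.0 - mu + eps)
    return -2.0 * np.sum(ll * mask, axis=-1)


def fit_logistic_batch(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta_max: float = BETA_MAX,
) -> BatchGlmResult:
    """Fit ``B`` logistic regressions by damped Newton iteration.

    Parameters
    ----------
    X : (B, n, p) stacked design matrices.
    y : (n,) or (B, n) binary outcome in {0, 1}.
    mask : optional boolean (B, n) or (n,); False drops a sample from
        the corresponding fit (complete-case handling).
    max_iter, tol : Newton iteration controls; convergence is declared
        when the max absolute step is below ``tol``.
    beta_max : coefficient magnitude beyond which the fit is flagged as
        separated/non-converged.

    Notes
    -----
    Step-halving is applied per batch element whenever a full Newton
    step would increase the deviance, so the deviance is monotonically
    non-increasing; elements whose information matrix becomes singular
    (e.g. a constant regressor) are frozen and flagged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise DimensionError(f"X must be (B, n, p); got shape {X.shape}")
    B, n, p = X.shape
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = np.broadcast_to(y, (B, n))
    if y.shape != (B, n):
        raise DimensionError(f"y shape {y.shape} incompatible with X {X.shape}")
    if mask is None:
        m = np.ones((B, n), dtype=float)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 1:
            mask = np.broadcast_to(mask, (B, n))
        m = mask.astype(float)

    beta = np.zeros((B, p))
    ok = np.ones(B, dtype=bool)  # information matrix invertible so far
    dev = _deviance(y, np.full((B, n), 0.5), m)
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        eta = np.einsum("bnp,bp->bn", X, beta)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None) * m
        score = np.einsum("bnp,bn->bp", X, (y - mu) * m)
        info = np.einsum("bnp,bn,bnq->bpq", X, w, X)
        step = np.full((B, p), np.nan)
        # batched solve; fall back element-wise where singular
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for b in range(B):
                try:
                    step[b] = np.linalg.solve(info[b], score[b])
                except np.linalg.LinAlgError:
                    ok[b] = False
        bad = ~np.isfinite(step).all(axis=1)
        ok &= ~bad
        step[~ok] = 0.0

        # per-element step halving against the deviance
        cand = beta + step
        dev_new = _deviance(y, expit(np.einsum("bnp,bp->bn", X, cand)), m)
        shrink = (dev_new > dev + 1e-10) & ok
        halvings = 0
        while shrink.any() and halvings < 10:
            step[shrink] *= 0.5
            cand = beta + step
            dev_new = _deviance(y, expit(np.einsum("bnp,bp->bn", X, cand)), m)
            shrink = (dev_new > dev + 1e-10) & ok
            halvings += 1
        beta = cand
        dev = dev_new
        if np.max(np.abs(step)) < tol:
            break

    diverged = np.abs(beta).max(axis=1) > beta_max
    converged = ok & ~diverged & (np.max(np.abs(step), axis=1) < np.sqrt(tol))

    # Wald SEs from the observed information at the final estimate
    eta = np.einsum("bnp,bp->bn", X, beta)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None) * m
    info = np.einsum("bnp,bn,bnq->bpq", X, w, X)
    se = np.full((B, p), np.nan)
    for b in range(B):
        if not ok[b]:
            continue
        try:
            cov = np.linalg.inv(info[b])
            d = np.diag(cov)
            se[b] = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            ok[b] = False
            converged[b] = False

    return BatchGlmResult(
        beta=beta,
        se=se,
        converged=converged,
        n_iter=n_iter,
        n_used=m.sum(axis=1).astype(int),
    )
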