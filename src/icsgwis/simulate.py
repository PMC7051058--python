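"""Synthetic two-stage cohorts for age-by-genotype interaction analysis.

The generative model is the one underlying the study's post-hoc power
calculation: biallelic genotypes drawn under Hardy-Weinberg equilibrium
at a given minor-allele frequency, a standard-normal "transformed age"
exposure, and a binary treatment-response outcome drawn from

    logit P(Y = 1 | G, E) = beta0 + betaG*G + betaE*E + betaI*G*E

with default coefficients beta0 = -0.32, betaG = 0.17, betaE = 0.97 and
MAF = 0.49 (the estimates for the top interaction signal), split into a
discovery stage of n = 783 and a replication stage of n = 538.

The single-SNP model is generalised to ``n_variants`` columns with a
designated causal subset so that the genome-wide filtering stages have a
testable target: non-causal variants are independent HWE noise with no
effect on the outcome.

Randomness is organised as named, independent streams spawned from one
root seed (genotypes / exposure / outcome / missingness / covariates,
with one sub-stream per variant inside the genotype stream), so changing
the number of variants never perturbs the exposure or outcome draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DimensionError, InvalidParameterError

_STREAMS = ("genotypes", "exposure", "outcome", "missingness", "covariates")


def _rngs(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


@dataclass
class SimulationParams:
    """Coefficients and sizes of the outcome-generating model.

    Defaults are the fitted values for the strongest observed
    age-by-genotype interaction signal; ``betaI`` is a free signed
    parameter (the reported effect's sign is ambiguous, so neither sign
    is privileged).
    """

    beta0: float = -0.32
    betaG: float = 0.17
    betaE: float = 0.97
    betaI: float = 0.0
    maf: float = 0.49
    n_samples: int = 783
    n_variants: int = 1
    n_causal: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta0", "betaG", "betaE", "betaI"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if not 0.0 < self.maf < 1.0:
            raise InvalidParameterError(f"maf must lie in (0, 1); got {self.maf}")
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")
        if self.n_variants < 1:
            raise InvalidParameterError("n_variants must be >= 1")
        if not 0 <= self.n_causal <= self.n_variants:
            raise InvalidParameterError("need 0 <= n_causal <= n_variants")


@dataclass
class GenotypeMatrix:
    """Samples x variants additive minor-allele dosages with a missingness mask.

    ``dosages`` keeps the drawn value even where ``missing`` is True;
    consumers must honour the mask (``dosages_with_nan`` does).
    """

    dosages: np.ndarray
    missing: np.ndarray
    variants: pd.DataFrame  # columns: id, chrom, pos, major, minor, info_score
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DimensionError("dosages must be 2-D (samples x variants)")
        if self.missing is None:
            self.missing = np.zeros_like(self.dosages, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.dosages.shape:
            raise DimensionError("missing mask must match dosage shape")
        if not self.samples:
            self.samples = [f"S{i:06d}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosages_with_nan(self) -> np.ndarray:
        out = self.dosages.copy()
        out[self.missing] = np.nan
        return out

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            missing=self.missing[:, keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    exposure: np.ndarray  # standard-normal scale ("transformed age")
    age: np.ndarray  # raw years, monotone in exposure
    covariates: pd.DataFrame  # sex, bmi, study
    outcome: np.ndarray  # 1 = poor responder (exacerbation), 0 = good
    stage_label: str = "discovery"
    params: SimulationParams | None = None
    causal_index: np.ndarray | None = None


def default_variant_table(n_variants: int, chrom: str = "1", start: int = 10_000,
                          spacing: int = 1_000) -> pd.DataFrame:
    pos = start + spacing * np.arange(n_variants)
    return pd.DataFrame(
        {
            "id": [f"var{j:05d}" for j in range(n_variants)],
            "chrom": chrom,
            "pos": pos,
            "major": "A",
            "minor": "C",
            "info_score": 1.0,
        }
    )


def simulate_genotypes(
    n_samples: int,
    maf_per_variant,
    seed: int,
    variants: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Draw HWE genotypes: each dosage is Binomial(2, maf), i.e. the sum of
    two independent Bernoulli(maf) allele draws.

    One RNG sub-stream per variant, so column j is invariant to the
    total number of variants requested.
    """
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    mafs = np.atleast_1d(np.asarray(maf_per_variant, dtype=float))
    if np.any((mafs <= 0.0) | (mafs >= 1.0)):
        raise InvalidParameterError("every MAF must lie strictly in (0, 1)")
    streams = _rngs(seed)["genotypes"].spawn(len(mafs))
    dos = np.empty((n_samples, len(mafs)))
    for j, (maf, ss) in enumerate(zip(mafs, streams)):
        dos[:, j] = np.random.default_rng(ss).binomial(2, maf, size=n_samples)
    if variants is None:
        variants = default_variant_table(len(mafs))
    return GenotypeMatrix(dosages=dos, missing=np.zeros_like(dos, dtype=bool),
                          variants=variants)


def simulate_exposure(n_samples: int, seed: int) -> np.ndarray:
    """I.i.d. standard-normal exposure (the transformed-age scale)."""
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    return np.random.default_rng(_rngs(seed)["exposure"]).standard_normal(n_samples)


def exposure_to_age(exposure: np.ndarray) -> np.ndarray:
    """Map a standard-normal exposure to plausible raw ages (years).

    A log-normal back-transform: strictly monotone, right-skewed, spanning
    childhood through adulthood, so a rank-based inverse-normal transform of
    the returned ages recovers the exposure up to rank equivalence.
    """
    return np.exp(2.9 + 0.55 * np.asarray(exposure, dtype=float))


def simulate_covariates(n_samples: int, seed: int,
                        studies: tuple[str, ...] = ("trial_a", "trial_b", "biobank")
                        ) -> pd.DataFrame:
    """Sex ~ Bernoulli(0.5), BMI ~ Normal(26, 4^2), study ~ uniform categorical.

    Drawn independently of genotype and exposure (no confounding by default).
    """
    rng = np.random.default_rng(_rngs(seed)["covariates"])
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n_samples),
            "bmi": rng.normal(26.0, 4.0, size=n_samples),
            "study": rng.choice(list(studies), size=n_samples),
        }
    )


def simulate_outcome(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    params: SimulationParams,
    seed: int,
    causal_index: np.ndarray | None = None,
) -> np.ndarray:
    """Bernoulli outcome from the logistic interaction model.

    ``genotypes`` may be a single dosage vector or an (n_samples,
    n_variants) matrix; in the latter case the linear predictor sums
    betaG*G_j + betaI*G_j*E over the causal columns only.
    """
    G = np.asarray(genotypes, dtype=float)
    E = np.asarray(exposure, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[0] != E.shape[0]:
        raise DimensionError(
            f"genotypes ({G.shape[0]}) and exposure ({E.shape[0]}) differ in length")
    if causal_index is None:
        causal_index = np.arange(min(params.n_causal, G.shape[1]))
    Gc = G[:, causal_index]
    eta = (params.beta0
           + params.betaG * Gc.sum(axis=1)
           + params.betaE * E
           + params.betaI * (Gc * E[:, None]).sum(axis=1))
    p = expit(eta)
    rng = np.random.default_rng(_rngs(seed)["outcome"])
    return (rng.random(E.shape[0]) < p).astype(np.int8)


def inject_missingness(genotypes: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask entries uniformly at random at the given expected rate."""
    if not 0.0 <= rate < 1.0:
        raise InvalidParameterError(f"missingness rate must lie in [0, 1); got {rate}")
    if rate == 0.0:
        return genotypes
    rng = np.random.default_rng(_rngs(seed)["missingness"])
    extra = rng.random(genotypes.dosages.shape) < rate
    return GenotypeMatrix(
        dosages=genotypes.dosages.copy(),
        missing=genotypes.missing | extra,
        variants=genotypes.variants.copy(),
        samples=list(genotypes.samples),
    )


def simulate_cohort(params: SimulationParams, stage_label: str = "discovery") -> SyntheticCohort:
    """One cohort under the full generative model (no missingness)."""
    mafs = np.full(params.n_variants, params.maf)
    gm = simulate_genotypes(params.n_samples, mafs, params.seed)
    E = simulate_exposure(params.n_samples, params.seed)
    causal = np.arange(params.n_causal)
    Y = simulate_outcome(gm.dosages, E, params, params.seed, causal_index=causal)
    cov = simulate_covariates(params.n_samples, params.seed)
    return SyntheticCohort(
        genotypes=gm,
        exposure=E,
        age=exposure_to_age(E),
        covariates=cov,
        outcome=Y,
        stage_label=stage_label,
        params=params,
        causal_index=causal,
    )


def simulate_two_stage_study(
    params_disc: SimulationParams,
    params_rep: SimulationParams | None = None,
    concordant: bool = True,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Independent discovery and replication cohorts.

    When ``concordant`` is False the causal interaction coefficient's
    sign is flipped in the replication stage, to exercise the
    direction-concordance gate downstream.
    """
    if params_rep is None:
        params_rep = replace(params_disc, n_samples=538, seed=params_disc.seed + 1)
    if params_rep.seed == params_disc.seed:
        params_rep = replace(params_rep, seed=params_disc.seed + 1)
    if not concordant:
        params_rep = replace(params_rep, betaI=-params_rep.betaI)
    disc = simulate_cohort(params_disc, stage_label="discovery")
    rep = simulate_cohort(params_rep, stage_label="replication")
    return disc, rep


def simulate_structured_genotypes(
    n_samples: int,
    n_variants: int,
    seed: int,
    fst_shift: float = 0.15,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two planted subpopulations with shifted allele frequencies.

    QC test fixture only (the main generator is structure-free): half the
    samples draw from frequencies p, half from clip(p + shift) with the
    shift's sign alternating per variant. Returns the matrix and the
    0/1 subpopulation labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = rng.uniform(0.2, 0.8, size=n_variants)
    sign = np.where(rng.random(n_variants) < 0.5, 1.0, -1.0)
    p2 = np.clip(base + sign * fst_shift, 0.02, 0.98)
    labels = (np.arange(n_samples) >= n_samples // 2).astype(int)
    freqs = np.where(labels[:, None] == 0, base[None, :], p2[None, :])
    dos = rng.binomial(2, freqs).astype(float)
    return (
        GenotypeMatrix(dosages=dos, missing=np.zeros_like(dos, dtype=bool),
                       variants=default_variant_table(n_variants)),
        labels,
    )
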