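"""Interaction-engine checks: transform, ML fit, scan calibration, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, norm, rankdata

from icsgwis.errors import (
    DegenerateOutcomeError,
    InvalidDataError,
    InvalidParameterError,
)
from icsgwis.gwis import (
    InteractionModelSpec,
    encode_covariates,
    fit_interaction_model,
    genomic_lambda,
    inverse_normal_transform,
    qq_table,
    run_gwis,
    wald_p_from_or_ci,
)
from icsgwis.simulate import SimulationParams, simulate_cohort


class TestInverseNormalTransform:
    def test_single_value_maps_to_zero(self):
        np.testing.assert_allclose(inverse_normal_transform([7.0]), [0.0], atol=1e-12)

    def test_three_values_blom_quantiles(self):
        z = norm.ppf((3 - 0.375) / 3.25)
        np.testing.assert_allclose(inverse_normal_transform([5, 10, 15]),
                                   [-z, 0.0, z], atol=1e-12)

    def test_all_equal_maps_to_zeros(self):
        np.testing.assert_allclose(inverse_normal_transform([3.0] * 7), np.zeros(7),
                                   atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidDataError):
            inverse_normal_transform([1.0, np.nan])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_rank_preserving_and_idempotent(self, values):
        v = np.asarray(values)
        t = inverse_normal_transform(v)
        np.testing.assert_array_equal(rankdata(v), rankdata(t))
        np.testing.assert_allclose(inverse_normal_transform(t), t, atol=1e-10)


def _hand_dataset():
    # 12 samples, mixed classes, verified non-separated
    g = np.array([1, 1, 0, 0, 2, 2, 1, 1, 1, 2, 2, 0], dtype=float)
    e = np.array([-2.33, -0.22, -1.25, -0.73, -0.54, -0.32, 0.41, 1.04,
                  -0.13, 1.37, -0.67, 0.35])
    y = np.array([0, 1, 0, 0, 0, 0, 0, 1, 1, 1, 0, 1], dtype=float)
    return y, g, e


class TestFitInteractionModel:
    def test_matches_statsmodels_ml(self):
        """IRLS estimates agree with an independent ML fitter to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        y, g, e = _hand_dataset()
        X = np.column_stack([np.ones_like(g), g, e, g * e])
        ref = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
        res = fit_interaction_model(y, g, e)
        np.testing.assert_allclose(
            [res.beta_g, res.beta_e, res.beta_int],
            ref.params[1:], atol=1e-6)
        np.testing.assert_allclose(res.se, ref.bse[3], atol=1e-6)

    def test_parameter_recovery_moderate_n(self):
        params = SimulationParams(betaI=-0.875, n_samples=20_000, seed=31)
        c = simulate_cohort(params)
        res = fit_interaction_model(c.outcome, c.genotypes.dosages[:, 0], c.exposure)
        assert res.converged
        assert abs(res.beta_int - (-0.875)) < 0.1

    def test_or_and_ci_consistent(self):
        y, g, e = _hand_dataset()
        res = fit_interaction_model(y, g, e)
        assert res.or_int == pytest.approx(np.exp(res.beta_int))
        assert res.ci_low <= res.or_int <= res.ci_high
        assert 0.0 < res.p_two_sided <= 1.0

    def test_constant_dosage_flagged(self):
        y, _, e = _hand_dataset()
        res = fit_interaction_model(y, np.zeros_like(e), e)
        assert not res.converged

    def test_one_class_outcome_raises(self):
        _, g, e = _hand_dataset()
        with pytest.raises(DegenerateOutcomeError):
            fit_interaction_model(np.ones_like(g), g, e)


class TestRunGwis:
    def test_null_pvalues_uniform(self):
        params = SimulationParams(betaI=0.0, n_samples=800, n_variants=1000,
                                  n_causal=0, seed=32)
        c = simulate_cohort(params)
        res = run_gwis(c, InteractionModelSpec(covariates=()))
        p = res.loc[res["converged"], "p"].to_numpy()
        assert kstest(p, "uniform").pvalue > 0.001

    def test_planted_signal_attains_min_p(self):
        params = SimulationParams(betaI=-1.0, n_samples=5000, n_variants=20,
                                  n_causal=1, seed=33)
        c = simulate_cohort(params)
        res = run_gwis(c)
        assert res.loc[res["p"].idxmin(), "id"] == c.genotypes.variants["id"].iloc[0]

    def test_permuted_outcome_rarely_exceeds_suggestive(self):
        """With outcome permuted, no variant clears 1e-5 in >=99/100 runs."""
        params = SimulationParams(betaI=-1.0, n_samples=600, n_variants=100,
                                  n_causal=1, seed=34)
        c = simulate_cohort(params)
        rng = np.random.default_rng(34)
        clean = 0
        for _ in range(100):
            yperm = rng.permutation(c.outcome)
            res = run_gwis(genotypes=c.genotypes, outcome=yperm,
                           exposure=c.exposure, spec=InteractionModelSpec(covariates=()))
            if not (res.loc[res["converged"], "p"] < 1e-5).any():
                clean += 1
        assert clean >= 99

    def test_invariant_to_sample_and_variant_order(self, planted_cohort):
        c = planted_cohort
        res = run_gwis(c)
        perm_s = np.random.default_rng(1).permutation(c.genotypes.n_samples)
        perm_v = np.array([3, 1, 4, 0, 2])
        gm2 = c.genotypes.subset_variants(perm_v)
        gm2.dosages = gm2.dosages[perm_s]
        gm2.missing = gm2.missing[perm_s]
        res2 = run_gwis(genotypes=gm2, outcome=c.outcome[perm_s],
                        exposure=c.exposure[perm_s],
                        covariates=c.covariates.iloc[perm_s].reset_index(drop=True))
        merged = res.merge(res2, on="id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["beta_int_a"], merged["beta_int_b"], atol=1e-7)
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], rtol=1e-6)

    def test_invariant_to_affine_covariate_encoding(self, planted_cohort):
        c = planted_cohort
        cov1 = pd.DataFrame({"bmi": c.covariates["bmi"]})
        cov2 = pd.DataFrame({"bmi": 2.0 * c.covariates["bmi"] + 3.0})
        r1 = run_gwis(genotypes=c.genotypes, outcome=c.outcome, exposure=c.exposure,
                      covariates=cov1, spec=InteractionModelSpec(covariates=("bmi",)))
        r2 = run_gwis(genotypes=c.genotypes, outcome=c.outcome, exposure=c.exposure,
                      covariates=cov2, spec=InteractionModelSpec(covariates=("bmi",)))
        np.testing.assert_allclose(r1["beta_int"], r2["beta_int"], atol=1e-7)
        np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-6)

    def test_missing_dosages_use_complete_cases(self, planted_cohort):
        c = planted_cohort
        gm = c.genotypes
        miss = gm.missing.copy()
        miss[:50, 0] = True
        gm2 = type(gm)(dosages=gm.dosages, missing=miss, variants=gm.variants,
                       samples=gm.samples)
        res = run_gwis(genotypes=gm2, outcome=c.outcome, exposure=c.exposure,
                       spec=InteractionModelSpec(covariates=()))
        assert res.loc[0, "n"] == gm.n_samples - 50
        # equals an explicit complete-case single fit
        keep = ~miss[:, 0]
        single = fit_interaction_model(c.outcome[keep], gm.dosages[keep, 0],
                                       c.exposure[keep])
        assert res.loc[0, "beta_int"] == pytest.approx(single.beta_int, abs=1e-7)


class TestWaldFromOrCi:
    def test_published_headline_cells(self):
        p = wald_p_from_or_ci(2.33, 1.61, 3.38)
        assert p == pytest.approx(7.8e-6, rel=0.05)
        assert p < 1e-5
        p_rep = wald_p_from_or_ci(0.51, 0.34, 0.77)
        assert p_rep == pytest.approx(1.2e-3, rel=0.05)
        assert p_rep < 0.05

    def test_or_one_gives_p_one(self):
        assert wald_p_from_or_ci(1.0, 0.5, 2.0) == pytest.approx(1.0)

    def test_bad_ordering_rejected(self):
        with pytest.raises(InvalidParameterError):
            wald_p_from_or_ci(2.0, 2.5, 3.0)


class TestGenomicLambda:
    def test_uniform_null_near_one(self, rng):
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert 0.98 <= lam <= 1.02

    def test_point_mass_half_is_exactly_one(self):
        assert genomic_lambda(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_halving_p_increases_lambda(self, rng):
        p = rng.uniform(size=10_000)
        assert genomic_lambda(p / 2) > genomic_lambda(p)

    def test_qq_table_monotone(self, rng):
        t = qq_table(rng.uniform(size=1000))
        assert (np.diff(t["expected_neglog10"]) <= 0).all()


def test_encode_covariates_one_hot_reference():
    df = pd.DataFrame({"sex": [0, 1, 0], "bmi": [20.0, 25.0, 30.0],
                       "study": ["a", "b", "c"]})
    C = encode_covariates(df)
    # sex + bmi + 2 study indicators (first level is reference)
    assert C.shape == (3, 4)
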