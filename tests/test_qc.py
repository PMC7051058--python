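"""Variant-filter checks: allele frequency, call rate, exact HWE, PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from icsgwis.errors import InvalidParameterError, UndefinedFrequencyError
from icsgwis.qc import (
    QCThresholds,
    apply_qc,
    call_rate,
    compute_maf,
    hwe_exact_test,
    pca_covariates,
)
from icsgwis.simulate import (
    GenotypeMatrix,
    default_variant_table,
    simulate_structured_genotypes,
)


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional het distribution.

    Independent of the package's log-space path: integer weights
    w(h) = 2^h * N! / (a! h! b!) over all attainable het counts, p-value
    = sum of weights <= observed weight over the total weight.
    """
    n = n_hom_ref + n_het + n_hom_alt
    ref = 2 * n_hom_ref + n_het
    alt = 2 * n_hom_alt + n_het
    rare, common = min(ref, alt), max(ref, alt)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a, b = (rare - h) // 2, (common - h) // 2
        if b < 0:
            continue
        weights[h] = (2**h) * math.factorial(n) // (
            math.factorial(a) * math.factorial(h) * math.factorial(b))
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs) / sum(weights.values())


class TestMafAndCallRate:
    def test_maf_hand_counts(self):
        assert compute_maf(np.array([0, 0, 1, 1, 2.0])) == pytest.approx(0.4)
        assert compute_maf(np.array([2, 2, 2, 1.0])) == pytest.approx(0.125)

    def test_monomorphic_maf_zero(self):
        assert compute_maf(np.zeros(10)) == 0.0

    def test_all_missing_maf_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            compute_maf(np.full(5, np.nan))

    def test_call_rate(self):
        assert call_rate(np.arange(10.0)) == 1.0
        v = np.arange(10.0)
        v[0] = np.nan
        assert call_rate(v) == pytest.approx(0.9)
        assert call_rate(np.full(4, np.nan)) == 0.0


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_small_example_matches_enumeration(self):
        assert hwe_exact_test(2, 2, 1) == pytest.approx(hwe_oracle(2, 2, 1), abs=1e-12)

    def test_random_triples_match_enumeration(self, rng):
        for _ in range(50):
            a, h, b = (int(x) for x in rng.integers(0, 51, size=3))
            if a + h + b == 0:
                continue
            assert hwe_exact_test(a, h, b) == pytest.approx(
                hwe_oracle(a, h, b), abs=1e-12)

    def test_p_in_unit_interval(self, rng):
        for _ in range(100):
            a, h, b = (int(x) for x in rng.integers(0, 30, size=3))
            if a + h + b == 0:
                continue
            p = hwe_exact_test(a, h, b)
            assert 0.0 < p <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(-1, 2, 3)


def _qc_fixture(n=300):
    """Five variants: one violating each rule, one clean."""
    rng = np.random.default_rng(99)
    clean = rng.binomial(2, 0.3, size=n).astype(float)
    rare = np.zeros(n)
    rare[:2] = 1.0  # MAF 2/600 < 1%
    all_het = np.ones(n)  # extreme heterozygote excess
    low_info = rng.binomial(2, 0.3, size=n).astype(float)
    sparse = rng.binomial(2, 0.3, size=n).astype(float)
    dos = np.column_stack([rare, sparse, all_het, low_info, clean])
    miss = np.zeros_like(dos, dtype=bool)
    miss[: int(0.2 * n), 1] = True  # 80% call rate on the sparse variant
    variants = default_variant_table(5)
    variants["info_score"] = [1.0, 1.0, 1.0, 0.5, 1.0]
    return GenotypeMatrix(dosages=dos, missing=miss, variants=variants)


class TestApplyQc:
    def test_each_rule_attributed(self):
        gm = _qc_fixture()
        kept, report = apply_qc(gm)
        assert report.n_input == 5 and report.n_pass == 1
        assert kept.variants["id"].tolist() == ["var00004"]
        assert report.exclusions == {"maf": 1, "call_rate": 1, "hwe": 1, "info": 1}
        failed = dict(zip(report.flags["id"], report.flags["fail_rules"]))
        assert failed["var00000"] == "maf"
        assert failed["var00001"] == "call_rate"
        assert failed["var00002"] == "hwe"
        assert failed["var00003"] == "info"

    def test_zero_thresholds_keep_everything_called(self):
        gm = _qc_fixture()
        kept, report = apply_qc(gm, QCThresholds(0.0, 0.0, 0.0, 0.0))
        assert report.n_pass == 5

    def test_threshold_boundary_passes(self):
        # call rate exactly 0.90 passes (exclusion is strictly below)
        n = 100
        dos = np.random.default_rng(3).binomial(2, 0.4, size=(n, 1)).astype(float)
        miss = np.zeros_like(dos, dtype=bool)
        miss[:10, 0] = True
        gm = GenotypeMatrix(dosages=dos, missing=miss,
                            variants=default_variant_table(1))
        _, report = apply_qc(gm)
        assert report.flags.loc[0, "call_rate"] == pytest.approx(0.9)
        assert "call_rate" not in report.flags.loc[0, "fail_rules"]

    def test_idempotent(self):
        gm = _qc_fixture()
        kept, _ = apply_qc(gm)
        kept2, report2 = apply_qc(kept)
        assert report2.n_pass == kept.n_variants
        np.testing.assert_array_equal(kept.dosages, kept2.dosages)

    def test_exclusion_counts_invariant_to_order(self):
        gm = _qc_fixture()
        perm = np.array([4, 2, 0, 3, 1])
        gm_perm = gm.subset_variants(perm)
        _, r1 = apply_qc(gm)
        _, r2 = apply_qc(gm_perm)
        assert r1.exclusions == r2.exclusions and r1.n_pass == r2.n_pass

    def test_missing_info_score_excluded(self):
        gm = _qc_fixture()
        gm.variants.loc[4, "info_score"] = np.nan
        _, report = apply_qc(gm)
        assert report.n_pass == 0
        assert "info_missing" in report.flags.loc[4, "fail_rules"]


class TestPca:
    def test_planted_structure_separated_by_pc1(self):
        gm, labels = simulate_structured_genotypes(500, 2000, seed=17)
        scores, _ = pca_covariates(gm, k=2)
        pred = (scores[:, 0] > np.median(scores[:, 0])).astype(int)
        acc = max(np.mean(pred == labels), np.mean(pred != labels))
        assert acc >= 0.95

    def test_scores_orthogonal(self):
        gm, _ = simulate_structured_genotypes(200, 500, seed=18)
        scores, evr = pca_covariates(gm, k=5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
        assert np.all(np.diff(evr) <= 1e-12)  # decreasing variance order

    def test_rank_one_matrix(self):
        base = np.array([0.0, 1, 2] * 30)
        dos = np.column_stack([base, base, base])
        gm = GenotypeMatrix(dosages=dos, missing=np.zeros_like(dos, dtype=bool),
                            variants=default_variant_table(3))
        with pytest.warns(UserWarning):
            scores, evr = pca_covariates(gm, k=2)
        assert scores.shape[1] == 1
        assert evr[0] == pytest.approx(1.0)
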