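"""Weighted LMM: phenotype construction, GRM, REML, and scan calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from recpipe.crossover import CrossoverRegion, MeiosisCallSet
from recpipe.gwas import (
    build_phenotypes,
    filter_snps,
    fit_null,
    genomic_inflation,
    grm,
    joint_fit,
    scan,
    significance_threshold,
)


def _callset(counts_by_meiosis, parent="p", sex="M", region_positions=None):
    meta = pd.DataFrame({
        "meiosis_id": list(counts_by_meiosis),
        "offspring": [f"o{i}" for i in range(len(counts_by_meiosis))],
        "parent": parent,
        "parent_sex": sex,
        "n_informative": 100,
        "n_calls": list(counts_by_meiosis.values()),
    })
    regions = []
    if region_positions:
        for mid, positions in region_positions.items():
            for left, right in positions:
                regions.append(CrossoverRegion(mid, sex, 1, 0, 1, left, right, 3, 3))
    return MeiosisCallSet(regions=regions, meta=meta)


class TestPhenotypes:
    def test_rate_is_mean_with_meiosis_weight(self):
        cs = _callset({"m1": 24, "m2": 26})
        out = build_phenotypes(cs, kind="rate")
        assert out["y"].iloc[0] == 25.0
        assert out["w"].iloc[0] == 2

    def test_chip_corrected_counts_used_when_given(self):
        cs = _callset({"m1": 10, "m2": 20})
        corrected = pd.DataFrame({"meiosis_id": ["m1", "m2"],
                                  "corrected_count": [20.0, 20.0]})
        out = build_phenotypes(cs, kind="rate", corrected_counts=corrected)
        assert out["y"].iloc[0] == 20.0

    def test_subtelomeric_threshold(self):
        """Crossover at 90% of the chromosome counts; one at 80% does not."""
        cs = _callset(
            {"m1": 2},
            region_positions={"m1": [(89_000_000, 91_000_000), (79_000_000, 81_000_000)]},
        )
        out = build_phenotypes(cs, kind="subtelomeric", chrom_lengths={1: 100_000_000})
        assert out["y"].iloc[0] == 1.0

    def test_phenotype_se_shrinks_with_weight(self):
        """Sires measured over many meioses: SD of the mean scales as 1/sqrt(w)."""
        rng = np.random.default_rng(0)
        means_few, means_many = [], []
        for _ in range(300):
            means_few.append(rng.poisson(25, size=2).mean())
            means_many.append(rng.poisson(25, size=50).mean())
        ratio = np.std(means_few) / np.std(means_many)
        assert ratio == pytest.approx(np.sqrt(50 / 2), rel=0.2)


class TestFilterSnps:
    def _map(self, n):
        return pd.DataFrame({"chrom": 1, "snp_id": [f"s{i}" for i in range(n)],
                             "pos_bp": np.arange(1, n + 1) * 1000})

    def test_low_maf_dropped(self):
        G = np.ones((1000, 2), dtype=np.int8) * 0
        G[:1, 0] = 1       # MAF 0.0005
        G[:500, 1] = 1     # MAF 0.25
        kept = filter_snps(G, self._map(2), maf_min=0.001)
        assert kept.tolist() == [1]

    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 200).astype(np.int8)
        G = np.column_stack([g, g, rng.integers(0, 3, 200)]).astype(np.int8)
        kept = filter_snps(G, self._map(3))
        assert 0 in kept and 1 not in kept

    def test_high_ld_pair_pruned(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, 500).astype(np.int8)
        near = base.copy()
        flip = rng.choice(500, 3, replace=False)
        near[flip] = (near[flip] + 1) % 3
        G = np.column_stack([
            rng.integers(0, 3, 500), base, near,
            rng.integers(0, 3, 500), rng.integers(0, 3, 500),
        ]).astype(np.int8)
        kept = filter_snps(G, self._map(5), r_max=0.95)
        assert len(kept) == 4 and 2 not in kept


class TestGrm:
    @staticmethod
    def _polymorphic(G):
        keep = ~(np.all(G == 0, axis=0) | np.all(G == 2, axis=0))
        return G[:, keep]

    def test_clone_rows_equal_diagonal(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, (5, 400)).astype(np.int8)
        G = self._polymorphic(np.vstack([g, g[:1]]))  # animal 5 clones animal 0
        A = grm(G)
        assert A[5, 0] == pytest.approx(A[0, 0], rel=1e-6)

    def test_unrelated_founders_near_zero_off_diagonal(self):
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.1, 0.9, 2000)
        G = (rng.random((40, 2000)) < freqs).astype(np.int8) + (
            rng.random((40, 2000)) < freqs
        ).astype(np.int8)
        A = grm(self._polymorphic(G))
        off = A[~np.eye(40, dtype=bool)]
        # centering on observed frequencies makes rows sum to ~0, so the
        # expected off-diagonal is -1/(n-1), not 0
        assert off.mean() == pytest.approx(-1 / 39, abs=0.01)

    def test_psd_and_symmetric(self):
        rng = np.random.default_rng(5)
        A = grm(rng.integers(0, 3, (30, 500)).astype(np.int8))
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() > -1e-10

    def test_monomorphic_rejected(self):
        G = np.zeros((10, 3), dtype=np.int8)
        G[:, 1] = 1
        with pytest.raises(ValueError):
            grm(G)


def _simulate_lmm(n=400, m=600, sigma_a2=1.0, sigma_e2=1.0, seed=0, w=None):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, m)
    G = ((rng.random((n, m)) < freqs).astype(int)
         + (rng.random((n, m)) < freqs).astype(int)).astype(np.int8)
    A = grm(G)
    L = np.linalg.cholesky(A + 1e-6 * np.eye(n))
    a = np.sqrt(sigma_a2) * (L @ rng.standard_normal(n))
    if w is None:
        w = np.ones(n)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2 / w)
    return G, A, a + e, w, rng


class TestFitNull:
    def test_zero_heritability_boundary(self):
        rng = np.random.default_rng(6)
        n = 300
        y = rng.standard_normal(n)
        A = grm(rng.integers(0, 3, (n, 800)).astype(np.int8))
        null = fit_null(y, np.ones(n), A)
        assert null.sigma_a2 / (null.sigma_a2 + null.sigma_e2) < 0.15

    def test_iid_variance_partition(self):
        """With w = 1 and A = I the fit reduces to an iid split:
        the variance components sum to var(y)."""
        rng = np.random.default_rng(7)
        y = rng.standard_normal(500) * 2.0
        null = fit_null(y, np.ones(500), np.eye(500))
        assert null.sigma_a2 + null.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_weight_rescaling_identity(self):
        """sigma_e^2 is defined relative to R = diag(1/w): at fixed data,
        doubling every w doubles the fitted sigma_e^2 while per-record
        residual variances sigma_e^2 / w stay unchanged (checked against the
        closed-form weighted residual variance in the pure-residual model)."""
        rng = np.random.default_rng(8)
        n = 200
        y = rng.standard_normal(n)
        w = rng.integers(1, 20, n).astype(float)
        A = np.zeros((n, n))  # no genetic component
        f1 = fit_null(y, w, A)
        f2 = fit_null(y, 2 * w, A)
        assert f2.sigma_e2 == pytest.approx(2.0 * f1.sigma_e2, rel=1e-3)
        # closed form: REML sigma_e^2 = weighted RSS about the weighted mean
        mu = np.average(y, weights=w)
        closed = np.sum(w * (y - mu) ** 2) / (n - 1)
        assert f1.sigma_e2 == pytest.approx(closed, rel=1e-3)

    def test_variance_recovery(self):
        G, A, y, w, _ = _simulate_lmm(n=500, m=900, sigma_a2=2.0, sigma_e2=1.0, seed=9)
        null = fit_null(y, w, A)
        h2 = null.sigma_a2 / (null.sigma_a2 + null.sigma_e2)
        assert h2 == pytest.approx(2 / 3, abs=0.15)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            fit_null(np.zeros(3), np.array([1.0, 0.0, 1.0]), np.eye(3))


class TestScan:
    def test_reduces_to_least_squares(self):
        """With w = 1 and A = I the scan equals fixed-variance least squares."""
        rng = np.random.default_rng(10)
        n, m = 250, 30
        G = rng.integers(0, 3, (n, m)).astype(np.int8)
        y = rng.standard_normal(n)
        null = fit_null(y, np.ones(n), np.eye(n))
        res = scan(null, G)
        sigma2 = null.sigma_a2 + null.sigma_e2  # total iid variance
        for j in range(0, m, 7):
            X = sm.add_constant(G[:, j].astype(float))
            ols = sm.OLS(y, X).fit()
            assert res.beta[j] == pytest.approx(ols.params[1], abs=1e-10)
            se_known = np.sqrt(sigma2 * ols.normalized_cov_params[1, 1])
            assert res.se[j] == pytest.approx(se_known, rel=1e-8)

    def test_null_calibration_and_type_one_error(self):
        G, A, y, w, _ = _simulate_lmm(n=600, m=800, sigma_a2=1.0, sigma_e2=1.0,
                                      seed=11, w=None)
        rng = np.random.default_rng(12)
        w = rng.integers(1, 30, 600).astype(float)
        y = y + rng.standard_normal(600) * np.sqrt(1.0 / w)
        null = fit_null(y, w, A)
        res = scan(null, G)
        lam = genomic_inflation(res.p)
        assert 0.9 < lam < 1.1
        alpha = 1e-3
        hits = int((res.p < alpha).sum())
        # binomial 99.9% envelope around 800 * alpha
        assert hits <= 8

    def test_qtl_beta_recovered_and_conditional_analysis(self):
        G, A, y, w, rng = _simulate_lmm(n=500, m=400, sigma_a2=0.5, sigma_e2=1.0, seed=13)
        qtl = 200
        beta_true = 0.8
        y = y + beta_true * G[:, qtl]
        null = fit_null(y, w, A)
        res = scan(null, G)
        assert abs(res.beta[qtl] - beta_true) < 2 * res.se[qtl]
        assert res.p[qtl] < significance_threshold(400)
        cond = scan(null, G, covariate_snps=[qtl])
        assert np.isnan(cond.p[qtl])
        # correlated neighbors lose significance once the causal SNP is fitted
        assert np.nanmin(cond.p) > res.p[qtl]

    def test_exact_reml_agrees_on_small_data(self):
        G, A, y, w, _ = _simulate_lmm(n=120, m=12, sigma_a2=0.5, sigma_e2=1.0, seed=14)
        null = fit_null(y, w, A)
        approx = scan(null, G)
        exact = scan(null, G, exact_reml=True)
        assert np.allclose(approx.beta, exact.beta, atol=0.05)

    def test_joint_fit_matches_single_snp_when_independent(self):
        rng = np.random.default_rng(15)
        n = 300
        G = rng.integers(0, 3, (n, 4)).astype(np.int8)
        y = 0.5 * G[:, 1] + rng.standard_normal(n)
        null = fit_null(y, np.ones(n), np.eye(n))
        single = scan(null, G)
        joint = joint_fit(null, G, [0, 1])
        b_joint = joint.set_index("snp_index")["beta"]
        assert b_joint[1] == pytest.approx(single.beta[1], abs=0.05)


class TestWeightingIdentity:
    def test_averaged_records_equal_expanded_records(self):
        """A mean-of-w-measurements record with weight w gives the same
        fixed-effect GLS estimate as the w unit-weight records it averages."""
        rng = np.random.default_rng(16)
        n_animals = 80
        g = rng.integers(0, 3, n_animals).astype(float)
        w = rng.integers(1, 6, n_animals)
        raw = [rng.normal(1.0 + 0.5 * g[i], 1.0, size=w[i]) for i in range(n_animals)]
        y_mean = np.array([r.mean() for r in raw])
        X = sm.add_constant(g)
        wls = sm.WLS(y_mean, X, weights=w).fit()
        y_long = np.concatenate(raw)
        X_long = sm.add_constant(np.repeat(g, w))
        ols = sm.OLS(y_long, X_long).fit()
        assert wls.params[1] == pytest.approx(ols.params[1], abs=1e-10)


def test_threshold_convention():
    assert significance_threshold(500) == pytest.approx(1e-4)
    # at the HD-imputed density of ~312,500 tests the Bonferroni level is 1.6e-7
    assert significance_threshold(312_500) == pytest.approx(1.6e-7)
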