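"""EM map construction vs closed forms and a grid-search MLE oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recpipe.crossover import CrossoverRegion
from recpipe.recmap import (
    RecombinationMap,
    chip_correct,
    em_fit,
    em_fit_indices,
    haldane_length,
    intervals_from_snp_map,
    map_summary,
)


def region_loglik(region_intervals, p):
    sums = np.array([p[np.asarray(r)].sum() for r in region_intervals])
    if np.any(sums <= 0):
        return -np.inf
    return float(np.log(sums).sum())


def mle_grid_oracle(region_intervals, n_intervals, n, sweeps=60):
    """Brute-force MLE by nested 1-D grid search over pairwise mass transfers.

    The log-likelihood sum_r log(sum_{i in r} p_i) is concave on the
    scaled simplex {p >= 0, sum p = R/n}, so iterated pairwise
    grid transfers converge to the global maximum.  Completely
    independent of the EM update.
    """
    R = len(region_intervals)
    total = R / n
    q = np.full(n_intervals, total / n_intervals)
    members = [np.asarray(r) for r in region_intervals]
    best = region_loglik(members, q)
    for _ in range(sweeps):
        improved = False
        for i in range(n_intervals):
            for j in range(i + 1, n_intervals):
                tot = q[i] + q[j]
                if tot <= 0:
                    continue
                # region sums are linear in g = new q_i: s_r = c_r + d_r g
                c = np.array([
                    q[r].sum() - q[i] * (i in set(r)) - q[j] * (j in set(r))
                    + tot * (j in set(r))
                    for r in members
                ])
                d = np.array([(i in set(r)) - (j in set(r)) for r in members], dtype=float)
                lo, hi = 0.0, tot
                for _level in range(8):
                    grid = np.linspace(lo, hi, 33)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        vals = np.where(
                            (c[:, None] + d[:, None] * grid[None, :]) > 0,
                            np.log(np.maximum(c[:, None] + d[:, None] * grid[None, :], 1e-300)),
                            -np.inf,
                        ).sum(axis=0)
                    k = int(np.argmax(vals))
                    lo = grid[max(0, k - 1)]
                    hi = grid[min(len(grid) - 1, k + 1)]
                g = 0.5 * (lo + hi)
                cand = q.copy()
                cand[i], cand[j] = g, tot - g
                v = region_loglik(members, cand)
                if v > best + 1e-12:
                    q, best = cand, v
                    improved = True
        if not improved:
            break
    return q, best


def random_instance(rng, max_intervals=4, max_regions=6):
    K = int(rng.integers(2, max_intervals + 1))
    R = int(rng.integers(1, max_regions + 1))
    regions = []
    for _ in range(R):
        a = int(rng.integers(0, K))
        b = int(rng.integers(a, K)) + 1
        regions.append(np.arange(a, b))
    n = int(rng.integers(R, 4 * R + 1))
    return regions, K, n


class TestEmClosedForms:
    def test_single_interval_regions_are_count_over_n(self):
        regions = [np.array([0]), np.array([0]), np.array([2])]
        p, info = em_fit_indices(regions, n=4, n_intervals=3)
        assert np.allclose(p, [0.5, 0.0, 0.25])
        assert info["converged"]

    def test_overlap_resolved_to_point_mass(self):
        """Regions {2,3} and {2} at n=2: all mass concentrates on interval 2."""
        p, _ = em_fit_indices([np.array([2, 3]), np.array([2])], n=2, n_intervals=4)
        assert p[2] == pytest.approx(1.0, abs=1e-6)
        assert p[3] == pytest.approx(0.0, abs=1e-6)

    def test_repeated_exact_interval(self):
        p, _ = em_fit_indices([np.array([3]), np.array([3])], n=4, n_intervals=5)
        assert p[3] == pytest.approx(0.5)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            em_fit_indices([np.array([], dtype=int)], n=1, n_intervals=2)

    def test_no_regions_zero_map(self):
        p, info = em_fit_indices([], n=10, n_intervals=4)
        assert np.all(p == 0) and info["converged"]


class TestEmInvariants:
    def test_conservation_and_monotone_likelihood(self):
        """Total EM mass times n equals the region count at every iteration,
        and the likelihood never decreases."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            regions, K, n = random_instance(rng)
            p, info = em_fit_indices(regions, n, K, track_likelihood=True)
            for mass in info["mass"]:
                assert mass == pytest.approx(len(regions), rel=1e-12)
            ll = info["loglik"]
            finite = [v for v in ll if np.isfinite(v)]
            assert all(b >= a - 1e-9 for a, b in zip(finite, finite[1:]))

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 5), st.integers(1, 6)).map(
                lambda ab: (min(ab[0], ab[1] - 1), max(ab[1], ab[0] + 1))
            ),
            min_size=1, max_size=8,
        ),
        n_extra=st.integers(0, 20),
    )
    def test_mass_conserved_for_arbitrary_region_sets(self, spans, n_extra):
        regions = [np.arange(a, b) for a, b in spans]
        n = len(regions) + n_extra
        p, info = em_fit_indices(regions, n, 6, track_likelihood=True)
        assert p.sum() * n == pytest.approx(len(regions), rel=1e-9)
        assert np.all(p >= 0)
        for mass in info["mass"]:
            assert mass == pytest.approx(len(regions), rel=1e-12)

    def test_matches_grid_search_mle(self):
        """EM attains the multinomial MLE found by brute-force grid search."""
        rng = np.random.default_rng(1)
        for _ in range(40):
            regions, K, n = random_instance(rng)
            p_em, _ = em_fit_indices(regions, n, K, tol=1e-12, max_iter=20000)
            q1, ll1 = mle_grid_oracle(regions, K, n)
            assert region_loglik(regions, p_em) >= ll1 - 1e-6
            # region sums are always identified
            s_em = np.array([p_em[r].sum() for r in regions])
            s_or = np.array([q1[r].sum() for r in regions])
            assert np.max(np.abs(s_em - s_or)) < 1e-4
            # parameters are identified iff membership + simplex constraint
            # pin down p uniquely (full column rank)
            M = np.zeros((len(regions) + 1, K))
            for r_i, r in enumerate(regions):
                M[r_i, r] = 1.0
            M[-1] = 1.0
            if np.linalg.matrix_rank(M) == K:
                assert np.max(np.abs(p_em - q1)) < 1e-4


def _mk_map(rates, chrom=None, starts=None, ends=None, n=10, sex="M"):
    rates = np.asarray(rates, dtype=float)
    k = rates.size
    iv = pd.DataFrame({
        "chrom": chrom if chrom is not None else [1] * k,
        "start_pos": starts if starts is not None else np.arange(k) * 1000 + 1,
        "end_pos": ends if ends is not None else np.arange(1, k + 1) * 1000,
    })
    return RecombinationMap(intervals=iv, rates=rates, n_meioses=n, sex=sex)


class TestEmFitOnRegions:
    def test_regions_map_onto_interval_grid(self):
        snp_map = pd.DataFrame({
            "chrom": [1, 1, 1, 2, 2],
            "snp_id": list("abcde"),
            "pos_bp": [100, 200, 300, 50, 150],
        })
        iv = intervals_from_snp_map(snp_map)
        assert len(iv) == 3  # two on chr1, one on chr2
        regions = [
            CrossoverRegion("m1", "M", 1, 0, 1, 100, 200, 3, 3),
            CrossoverRegion("m2", "M", 2, 0, 1, 50, 150, 3, 3),
        ]
        rmap = em_fit(regions, n=2, intervals=iv)
        assert rmap.rates[0] == pytest.approx(0.5)
        assert rmap.rates[2] == pytest.approx(0.5)
        assert rmap.total_morgans() == pytest.approx(1.0)

    def test_region_beyond_grid_rejected(self):
        snp_map = pd.DataFrame({"chrom": [1, 1], "snp_id": ["a", "b"], "pos_bp": [1, 2]})
        iv = intervals_from_snp_map(snp_map)
        bad = CrossoverRegion("m", "M", 1, 0, 5, 1, 2, 3, 3)
        with pytest.raises(ValueError):
            em_fit([bad], n=1, intervals=iv)


class TestChipCorrection:
    def _counts(self, values, category, sex="M"):
        return pd.DataFrame({
            "meiosis_id": [f"{category}{i}" for i in range(len(values))],
            "parent_sex": sex,
            "category": category,
            "count": values,
        })

    def test_low_density_category_factor(self):
        """A chip mix that sees 17.7 of the reference's 25.9 crossovers is
        scaled by 25.9/17.7."""
        df = pd.concat([self._counts([25.9] * 4, "ref"), self._counts([17.7] * 4, "3K")])
        corrected, corr = chip_correct(df, "ref")
        assert corr.factor("M", "3K") == pytest.approx(25.9 / 17.7)
        assert corr.factor("M", "3K") == pytest.approx(1.463, abs=0.001)

    def test_reference_factor_is_one(self):
        df = self._counts([10, 20, 30], "ref")
        _, corr = chip_correct(df, "ref")
        assert corr.factor("M", "ref") == 1.0

    def test_corrected_means_equalized(self):
        df = pd.concat([
            self._counts([10, 10], "low"), self._counts([20, 20], "ref"),
        ])
        corrected, _ = chip_correct(df, "ref")
        means = corrected.groupby("category")["corrected_count"].mean()
        assert means["low"] == pytest.approx(20.0)
        assert means["ref"] == pytest.approx(20.0)

    def test_sexes_corrected_separately(self):
        df = pd.concat([
            self._counts([20.0] * 3, "ref", "M"), self._counts([10.0] * 3, "low", "M"),
            self._counts([18.0] * 3, "ref", "F"), self._counts([12.0] * 3, "low", "F"),
        ])
        _, corr = chip_correct(df, "ref")
        assert corr.factor("M", "low") == pytest.approx(2.0)
        assert corr.factor("F", "low") == pytest.approx(1.5)


class TestHaldane:
    def test_zero_rate_zero_distance(self):
        out = haldane_length(_mk_map([0.0, 0.0]))
        assert out["haldane_morgans"].sum() == 0.0

    def test_quarter_rate(self):
        out = haldane_length(_mk_map([0.25]))
        assert out["haldane_morgans"].iloc[0] == pytest.approx(-0.5 * np.log(0.5), rel=1e-12)
        assert out["haldane_morgans"].iloc[0] == pytest.approx(0.3466, abs=1e-4)

    def test_adjusted_never_shorter_than_raw(self):
        rng = np.random.default_rng(4)
        rates = rng.uniform(0, 0.4, 50)
        out = haldane_length(_mk_map(rates))
        assert out["haldane_morgans"].sum() >= out["raw_morgans"].sum()
        out0 = haldane_length(_mk_map(np.zeros(5)))
        assert out0["haldane_morgans"].sum() == out0["raw_morgans"].sum() == 0.0

    def test_rate_at_half_rejected_with_interval_named(self):
        with pytest.raises(ValueError, match="0.5"):
            haldane_length(_mk_map([0.1, 0.5]))


class TestMapSummary:
    def test_identical_maps_perfectly_correlated(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0, 0.01, 30)
        m = _mk_map(rates, sex="M")
        f = _mk_map(rates.copy(), sex="F")
        out = map_summary(m, f)
        assert out["interval_rate_correlation"] == pytest.approx(1.0)

    def test_kb_per_cm_headline_scale(self):
        """2,516 Mb at 25.5 Morgans is ~986 kb/cM."""
        m = _mk_map([25.5], starts=[1], ends=[2_516_000_001])
        f = _mk_map([23.2], starts=[1], ends=[2_516_000_001])
        out = map_summary(m, f)
        assert out["genome_kb_per_cm_male"] == pytest.approx(986, abs=1.0)
        assert out["genome_kb_per_cm_female"] == pytest.approx(1085, abs=1.0)

    def test_interval_mismatch_rejected(self):
        with pytest.raises(ValueError):
            map_summary(_mk_map([0.1, 0.1]), _mk_map([0.1]))
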