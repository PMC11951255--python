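"""MR estimators against hand calculations and independent WLS oracles."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from cismr import (EstimationError, HarmonizedSet, LDMatrix, conmix, egger,
                   ivw, ivw_ld, mvmr_ivw, presso, weighted_median)
from conftest import consistent_harmonized, noisy_harmonized


def random_instance(j, seed, k=1):
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.3, 0.3, (j, k))
    sx = rng.uniform(0.005, 0.05, (j, k))
    by = rng.normal(0.0, 0.2, j)
    sy = rng.uniform(0.01, 0.2, j)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


class TestIVW:
    def test_single_variant_is_wald_ratio(self):
        h = HarmonizedSet.from_arrays([0.5], [0.01], [0.25], [0.1])
        est = ivw(h)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.scale_factor == 1.0

    def test_two_variant_hand_calculation(self):
        h = HarmonizedSet.from_arrays([1.0, 1.0], [0.01, 0.01],
                                      [0.1, 0.3], [0.1, 0.1])
        est = ivw(h)
        assert est.theta == pytest.approx(0.2)
        assert est.q_stat == pytest.approx(2.0)
        assert est.scale_factor == pytest.approx(np.sqrt(2))
        # fixed se sqrt(1/200) inflated by sqrt(2) -> 0.1
        assert est.se == pytest.approx(0.1)

    def test_matches_wls_oracle(self):
        for seed in range(20):
            h = random_instance(j=20, seed=seed)
            est = ivw(h)
            fit = sm.WLS(h.beta_outcome, h.beta_exposure,
                         weights=1.0 / h.se_outcome ** 2).fit()
            assert est.theta == pytest.approx(fit.params[0], rel=1e-10)

    def test_irrelevant_instruments_fatal(self):
        h = HarmonizedSet.from_arrays([0.0, 0.0], [0.01, 0.01],
                                      [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(EstimationError, match="irrelevant_instruments"):
            ivw(h)

    def test_random_effects_never_shrink_ci(self):
        for seed in range(10):
            h = random_instance(j=12, seed=100 + seed)
            est = ivw(h)
            se_fixed = np.sum(h.beta_exposure[:, 0] ** 2
                              / h.se_outcome ** 2) ** -0.5
            assert est.se >= se_fixed - 1e-15


class TestIVWLD:
    def test_identity_ld_equals_ivw(self):
        h = random_instance(j=8, seed=3)
        h.ld = LDMatrix([f"v{i + 1}" for i in range(8)], np.eye(8))
        a, b = ivw_ld(h), ivw(h)
        assert a.theta == pytest.approx(b.theta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_duplicated_variant_singular(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 1.0
        h = random_instance(j=3, seed=4)
        h.ld = LDMatrix(["v1", "v2", "v3"], r)
        with pytest.raises(EstimationError, match="singular_ld"):
            ivw_ld(h)

    def test_unbiased_under_ar1_ld(self):
        # consistent data with correlated noise: GLS estimate is unbiased
        rho, j, theta0 = 0.5, 10, 0.3
        idx = np.arange(j)
        r = rho ** np.abs(idx[:, None] - idx[None, :])
        chol = np.linalg.cholesky(r)
        rng = np.random.default_rng(5)
        x = rng.uniform(0.3, 1.0, j)
        sy = np.full(j, 0.05)
        estimates = []
        ld = LDMatrix([f"v{i + 1}" for i in range(j)], r)
        for _ in range(1000):
            y = theta0 * x + sy * (chol @ rng.standard_normal(j))
            h = HarmonizedSet.from_arrays(x, np.full(j, 1e-6), y, sy, ld=ld)
            estimates.append(ivw_ld(h).theta)
        assert abs(np.mean(estimates) - theta0) < 0.01


class TestEgger:
    def test_exact_linear_fit(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        h = HarmonizedSet.from_arrays(x, np.full(4, 0.01),
                                      0.05 + 0.4 * x, np.full(4, 0.02))
        slope, intercept = egger(h)
        assert slope.theta == pytest.approx(0.4, abs=1e-12)
        assert intercept.theta == pytest.approx(0.05, abs=1e-12)
        assert slope.q_stat == pytest.approx(0.0, abs=1e-18)
        assert slope.scale_factor == 1.0

    def test_orientation_flips_negative_exposure_betas(self):
        x = np.array([0.2, -0.4, 0.6, -0.8])
        y = 0.05 * np.sign(x) + 0.4 * x  # consistent after orientation
        h = HarmonizedSet.from_arrays(x, np.full(4, 0.01), y, np.full(4, 0.02))
        slope, intercept = egger(h)
        assert slope.theta == pytest.approx(0.4, abs=1e-12)
        assert intercept.theta == pytest.approx(0.05, abs=1e-12)

    def test_constant_exposure_unidentified(self):
        h = HarmonizedSet.from_arrays([0.5, 0.5, 0.5], [0.01] * 3,
                                      [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(EstimationError, match="unidentified"):
            egger(h)

    def test_matches_wls_oracle(self):
        for seed in range(20):
            h = random_instance(j=15, seed=200 + seed)
            slope, intercept = egger(h)
            flip = np.sign(h.beta_exposure[:, 0])
            x = h.beta_exposure[:, 0] * flip
            y = h.beta_outcome * flip
            fit = sm.WLS(y, sm.add_constant(x),
                         weights=1.0 / h.se_outcome ** 2).fit()
            assert intercept.theta == pytest.approx(fit.params[0], rel=1e-10)
            assert slope.theta == pytest.approx(fit.params[1], rel=1e-10)


class TestWeightedMedian:
    def _from_ratios(self, ratios, se_ratio=0.1):
        x = np.ones(len(ratios))
        return HarmonizedSet.from_arrays(x, np.full(len(ratios), 1e-8),
                                         np.asarray(ratios, float),
                                         np.full(len(ratios), se_ratio))

    def test_exact_hit_at_half(self):
        est = weighted_median(self._from_ratios([0.1, 0.2, 0.6]),
                              n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_interpolation_between_two(self):
        est = weighted_median(self._from_ratios([0.1, 0.3]).__class__
                              .from_arrays([1.0, 1.0, 1.0], [1e-8] * 3,
                                           [0.1, 0.1, 0.3], [0.1] * 3),
                              n_boot=100, seed=0)
        # positions 1/6, 1/2, 5/6 -> value at 0.5 is the middle ratio
        assert est.theta == pytest.approx(0.1)

    def test_two_point_interpolation_formula(self):
        # equal weights at ratios 0.1 and 0.3: positions 0.25/0.75 -> 0.2
        from cismr.estimators import _weighted_median
        assert _weighted_median(np.array([0.1, 0.3]),
                                np.array([1.0, 1.0])) == pytest.approx(0.2)

    def test_seed_reproducibility(self):
        h = noisy_harmonized(seed=5)
        a = weighted_median(h, n_boot=500, seed=42)
        b = weighted_median(h, n_boot=500, seed=42)
        assert a.se == b.se and a.theta == b.theta

    def test_breakdown_resistance(self):
        # 40% of weight displaced by +2: median stays near truth, IVW moves
        rng = np.random.default_rng(11)
        theta0, j = 0.3, 20
        x = rng.uniform(0.5, 1.0, j)
        y = theta0 * x + rng.normal(0, 0.02, j)
        y[:8] += 2.0 * x[:8]
        h = HarmonizedSet.from_arrays(x, np.full(j, 1e-6), y, np.full(j, 0.02))
        med = weighted_median(h, n_boot=500, seed=1)
        assert abs(med.theta - theta0) < 2 * med.se
        assert abs(ivw(h).theta - theta0) > 5 * med.se


class TestConmix:
    def _from_ratios(self, ratios, se=0.05):
        j = len(ratios)
        return HarmonizedSet.from_arrays(np.ones(j), np.full(j, 1e-8),
                                         np.asarray(ratios, float),
                                         np.full(j, se))

    def test_consensus(self):
        est = conmix(self._from_ratios([0.3] * 10, se=0.01))
        assert est.theta == pytest.approx(0.3)
        assert est.extra["valid"].all()
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_outliers_classified_invalid_matches_exhaustive_search(self):
        rng = np.random.default_rng(21)
        ratios = np.concatenate([rng.normal(0.3, 0.02, 7),
                                 rng.normal(1.5, 0.02, 3)])
        se = np.full(10, 0.05)
        h = self._from_ratios(ratios, se=0.05)
        est = conmix(h)
        assert est.theta == pytest.approx(0.3, abs=0.05)
        assert list(np.flatnonzero(~est.extra["valid"])) == [7, 8, 9]
        # oracle: best over all 2^J valid/invalid assignments of the same
        # likelihood, profiling theta over the valid subset's grid
        psi = est.extra["psi"]
        grid = np.linspace(ratios.min() - 0.25, ratios.max() + 0.25, 2001)

        def loglik(valid_mask, theta):
            ll = 0.0
            for rj, sj, v in zip(ratios, se, valid_mask):
                if v:
                    ll += -0.5 * ((rj - theta) / sj) ** 2 - np.log(sj)
                else:
                    var = psi ** 2 + sj ** 2
                    ll += -0.5 * rj ** 2 / var - 0.5 * np.log(var)
            return ll

        best = (-np.inf, None, None)
        for mask in itertools.product([True, False], repeat=10):
            if not any(mask):
                continue
            lls = [loglik(mask, t) for t in grid]
            i = int(np.argmax(lls))
            if lls[i] > best[0]:
                best = (lls[i], grid[i], mask)
        assert est.theta == pytest.approx(best[1], abs=0.01)
        assert tuple(est.extra["valid"]) == best[2]

    def test_large_psi_keeps_all_valid(self):
        rng = np.random.default_rng(22)
        h = self._from_ratios(rng.normal(0.3, 0.1, 8), se=0.05)
        est = conmix(h, psi=1e6)
        assert est.extra["valid"].all()
        # consensus of all ratios, IVW-like
        assert est.theta == pytest.approx(ivw(h).theta, abs=0.02)


class TestPresso:
    def test_seed_determinism(self):
        h = noisy_harmonized(seed=7, j=10)
        a = presso(h, seed=9)
        b = presso(h, seed=9)
        assert a[0] == b[0]
        assert (a[1] == b[1]).all()

    def test_planted_outlier_flagged_and_corrected(self):
        h = noisy_harmonized(theta=0.3, seed=8, j=12, se_y=0.02, se_x=1e-6)
        h.beta_outcome[4] += 10 * h.se_outcome[4]
        gp, flags, corrected = presso(h, seed=1)
        assert flags[4]
        assert gp < 0.05
        assert abs(corrected.theta - 0.3) < abs(ivw(h).theta - 0.3)

    def test_too_few_instruments(self):
        h = noisy_harmonized(j=3)
        with pytest.raises(EstimationError):
            presso(h)


class TestMVMR:
    def test_k1_equals_ivw(self):
        h = random_instance(j=10, seed=31)
        a = mvmr_ivw(h)[0]
        b = ivw(h)
        assert a.theta == pytest.approx(b.theta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-6)

    def test_orthogonal_blocks_match_univariable(self):
        rng = np.random.default_rng(32)
        jb = 8
        x1 = np.concatenate([rng.uniform(0.3, 1.0, jb), np.zeros(jb)])
        x2 = np.concatenate([np.zeros(jb), rng.uniform(0.3, 1.0, jb)])
        y = 0.4 * x1 - 0.2 * x2
        sy = np.full(2 * jb, 0.05)
        h = HarmonizedSet.from_arrays(np.column_stack([x1, x2]),
                                      np.full((2 * jb, 2), 0.01), y, sy,
                                      exposure_names=["e1", "e2"])
        ests = mvmr_ivw(h)
        h1 = HarmonizedSet.from_arrays(x1[:jb], np.full(jb, 0.01), y[:jb],
                                       sy[:jb])
        h2 = HarmonizedSet.from_arrays(x2[jb:], np.full(jb, 0.01), y[jb:],
                                       sy[jb:])
        assert ests[0].theta == pytest.approx(ivw(h1).theta, abs=1e-8)
        assert ests[1].theta == pytest.approx(ivw(h2).theta, abs=1e-8)

    def test_matches_wls_oracle(self):
        for seed in range(10):
            h = random_instance(j=25, seed=300 + seed, k=3)
            ests = mvmr_ivw(h)
            fit = sm.WLS(h.beta_outcome, h.beta_exposure,
                         weights=1.0 / h.se_outcome ** 2).fit()
            for m in range(3):
                assert ests[m].theta == pytest.approx(fit.params[m], rel=1e-9)

    def test_collinear_fatal(self):
        x = np.linspace(0.1, 1.0, 8)
        h = HarmonizedSet.from_arrays(np.column_stack([x, 3 * x]),
                                      np.full((8, 2), 0.01),
                                      0.2 * x, np.full(8, 0.05),
                                      exposure_names=["e1", "e2"])
        with pytest.raises(EstimationError, match="collinear_exposures"):
            mvmr_ivw(h)


class TestConsistentData:
    """With all per-variant ratios exactly theta0 every estimator recovers
    theta0 with zero heterogeneity."""

    def test_all_estimators_exact(self):
        theta0 = 0.4
        h = consistent_harmonized(theta=theta0, j=8)
        assert ivw(h).theta == pytest.approx(theta0, rel=1e-12)
        assert ivw(h).q_stat == pytest.approx(0.0, abs=1e-18)
        assert ivw(h).scale_factor == 1.0
        slope, intercept = egger(h)
        assert slope.theta == pytest.approx(theta0, rel=1e-9)
        assert intercept.theta == pytest.approx(0.0, abs=1e-10)
        assert weighted_median(h, n_boot=50, seed=0).theta \
            == pytest.approx(theta0, rel=1e-12)
        assert conmix(h).theta == pytest.approx(theta0, rel=1e-12)
        h.ld = LDMatrix([f"v{i + 1}" for i in range(8)], np.eye(8))
        assert ivw_ld(h).theta == pytest.approx(theta0, rel=1e-12)

    def test_odds_ratio_monotone_in_theta(self):
        ests = [ivw(consistent_harmonized(theta=t, j=5))
                for t in (-0.5, -0.1, 0.0, 0.2, 0.6)]
        ors = [e.odds_ratio for e in ests]
        assert ors == sorted(ors)
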