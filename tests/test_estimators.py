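"""Estimator correctness against independent oracles and exact fixtures."""

import numpy as np
import pytest
import statsmodels.api as sm

from pleiomr import montecarlo
from pleiomr.errors import (CollinearityError, ConfigurationError,
                            DivisionError, InsufficientSnpsError)
from pleiomr.estimators import (egger, fit_ivw, fit_mv_ivw,
                                fit_weighted_median, ivw, mv_ivw, simex_egger,
                                wald_ratio, weighted_median, weighted_mode)
from pleiomr.summary_io import MvHarmonizedSet

from conftest import make_hset


def mv_set(BZX, bzy, se_zy, se_zx=None):
    import pandas as pd
    BZX = np.asarray(BZX, dtype=float)
    k, K = BZX.shape
    cols = {"rsid": [f"rs{i}" for i in range(k)]}
    for j in range(K):
        cols[f"beta_zx_{j}"] = BZX[:, j]
        cols[f"se_zx_{j}"] = (se_zx[:, j] if se_zx is not None
                              else np.full(k, 0.01))
    cols["beta_zy"] = np.asarray(bzy, dtype=float)
    cols["se_zy"] = np.asarray(se_zy, dtype=float)
    return MvHarmonizedSet(exposure_ids=[f"E{j}" for j in range(K)],
                           outcome_id="Y", table=pd.DataFrame(cols))


class TestWaldRatio:
    def test_ratio_and_delta_method_se(self):
        e = wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert e.beta == pytest.approx(2.0)
        assert e.se == pytest.approx(0.5)
        assert e.ci_low == pytest.approx(2.0 - 1.959964 * 0.5)

    def test_null_numerator(self):
        assert wald_ratio(0.1, 0.02, 0.0, 0.05).beta == 0.0

    def test_homogeneity_in_outcome_scale(self):
        e1 = wald_ratio(0.1, 0.02, 0.2, 0.05)
        e2 = wald_ratio(0.1, 0.02, 0.2 * 3, 0.05 * 3)
        assert e2.beta == pytest.approx(3 * e1.beta)
        assert e2.se == pytest.approx(3 * e1.se)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(DivisionError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)


class TestIvw:
    def test_exact_proportionality(self):
        h = make_hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01] * 3)
        fixed = ivw(h, model="fixed")
        random = ivw(h, model="multiplicative_random")
        assert fixed.beta == pytest.approx(0.5, rel=1e-12)
        assert fixed.info["q"] == pytest.approx(0.0, abs=1e-18)
        assert fixed.se == pytest.approx(random.se)

    def test_single_snp_reduces_to_wald_ratio(self):
        h = make_hset([0.1], [0.05], [0.02], se_zx=[0.01])
        e = ivw(h)
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert (e.beta, e.se) == (w.beta, w.se)

    def test_matches_zero_intercept_wls_oracle(self):
        bzx = np.array([0.1, 0.2, 0.3])
        bzy = np.array([0.06, 0.09, 0.16])
        se_zy = np.array([0.01, 0.02, 0.01])
        h = make_hset(bzx, bzy, se_zy)
        fit = sm.WLS(bzy, bzx[:, None], weights=1 / se_zy ** 2).fit()
        assert ivw(h).beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_analytic_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(9)
        bzx = rng.normal(0.2, 0.05, 30)
        bzy = rng.normal(0.1, 0.05, 30)
        se_zy = rng.uniform(0.01, 0.05, 30)
        w = bzx ** 2 / se_zy ** 2
        expected = np.sum(w * bzy / bzx) / np.sum(w)
        beta, _, _ = fit_ivw(bzx, bzy, se_zy)
        assert beta == pytest.approx(expected, rel=1e-10)

    def test_zero_exposure_effect_names_snp(self):
        h = make_hset([0.1, 0.0, 0.2], [0.05, 0.05, 0.1], [0.01] * 3,
                      rsids=["a", "bad", "c"])
        with pytest.raises(DivisionError, match="bad"):
            ivw(h)


class TestEgger:
    def test_line_through_origin(self):
        h = make_hset([0.1, 0.2, 0.3, 0.4], [0.05, 0.10, 0.15, 0.20],
                      [0.01] * 4)
        e = egger(h)
        assert e.beta == pytest.approx(0.5, rel=1e-10)
        assert e.intercept == pytest.approx(0.0, abs=1e-14)

    def test_exact_affine_relation(self):
        bzx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(bzx, 0.5 * bzx + 0.02, [0.01] * 4)
        e = egger(h)
        assert e.beta == pytest.approx(0.5, rel=1e-10)
        assert e.intercept == pytest.approx(0.02, rel=1e-10)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        bzx = np.abs(rng.normal(0.3, 0.1, 5))
        se_zy = rng.uniform(0.02, 0.08, 5)
        bzy = 0.4 * bzx + 0.01 + rng.normal(0, 0.3, 5)  # noisy: sigma2 > 1
        h = make_hset(bzx, bzy, se_zy)
        X = sm.add_constant(bzx)
        fit = sm.WLS(bzy, X, weights=1 / se_zy ** 2).fit()
        e = egger(h)
        assert e.intercept == pytest.approx(fit.params[0], rel=1e-8)
        assert e.beta == pytest.approx(fit.params[1], rel=1e-8)
        assert fit.scale > 1  # residual scaling active on both routes
        assert e.intercept_se == pytest.approx(fit.bse[0], rel=1e-8)
        assert e.se == pytest.approx(fit.bse[1], rel=1e-8)

    def test_orientation_flips_negative_exposure_effects(self):
        bzx = np.array([0.1, -0.2, 0.3, -0.4])
        bzy = 0.5 * bzx
        e = egger(make_hset(bzx, bzy, [0.01] * 4))
        assert e.beta == pytest.approx(0.5, rel=1e-10)
        assert e.intercept == pytest.approx(0.0, abs=1e-14)

    def test_too_few_snps(self):
        with pytest.raises(InsufficientSnpsError):
            egger(make_hset([0.1, 0.2], [0.05, 0.1], [0.01] * 2))


class TestSimexEgger:
    def _noisy_set(self, seed=0, k=30):
        rng = np.random.default_rng(seed)
        bzx = np.abs(rng.normal(0.2, 0.1, k))
        bzy = 0.5 * bzx + rng.normal(0, 0.02, k)
        return make_hset(bzx, bzy, np.full(k, 0.02),
                         se_zx=np.full(k, 0.05))

    def test_no_measurement_error_equals_plain_egger_exactly(self):
        h = make_hset([0.1, 0.2, 0.3, 0.4], [0.06, 0.11, 0.14, 0.21],
                      [0.01] * 4, se_zx=[0.0] * 4)
        plain = egger(h)
        corrected = simex_egger(h, seed=1)
        assert corrected.beta == plain.beta
        assert corrected.se == plain.se
        assert corrected.intercept == plain.intercept

    def test_reproducible_for_fixed_seed(self):
        h = self._noisy_set()
        a = simex_egger(h, b_reps=200, seed=42)
        b = simex_egger(h, b_reps=200, seed=42)
        assert (a.beta, a.se, a.intercept) == (b.beta, b.se, b.intercept)
        c = simex_egger(h, b_reps=200, seed=43)
        assert c.beta != a.beta

    def test_degenerate_lambda_grid_rejected(self):
        h = self._noisy_set()
        with pytest.raises(ConfigurationError):
            simex_egger(h, lambda_grid=(0.0, 1.0), seed=1)
        with pytest.raises(ConfigurationError):
            simex_egger(h, lambda_grid=(0.5, 1.0, 1.5), seed=1)

    def test_corrects_regression_dilution_on_average(self):
        # heavy exposure measurement error attenuates the Egger slope;
        # the extrapolated estimate recovers most of it
        res = montecarlo.simex_improvement(n_reps=15, seed=5, b_reps=100)
        theta = res["theta"]
        assert res["mean_plain_egger_slope"] < theta - 0.02
        assert (abs(res["mean_simex_slope"] - theta)
                < abs(res["mean_plain_egger_slope"] - theta))


class TestWeightedMedian:
    def test_constant_ratios(self):
        bzx = np.array([0.1, 0.2, 0.4])
        e = weighted_median(make_hset(bzx, 0.7 * bzx, [0.01, 0.03, 0.02]),
                            n_boot=500, seed=1)
        assert e.beta == pytest.approx(0.7, rel=1e-12)

    def test_symmetric_equal_weights_pick_middle_ratio(self):
        # equal weights need equal bzx and equal se_zy
        bzx = np.array([1.0, 1.0, 1.0])
        bzy = np.array([0.1, 0.5, 0.9])
        e = weighted_median(make_hset(bzx, bzy, [0.1] * 3), n_boot=500, seed=1)
        assert e.beta == pytest.approx(0.5, rel=1e-12)

    def test_matches_hand_enumerated_interpolation_oracle(self):
        # ratios 0.2..1.0 with unequal weights; oracle follows the
        # cumulative-weight interpolation rule step by step
        ratios = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        weights = np.array([4.0, 1.0, 1.0, 2.0, 2.0])
        se_zy = 0.1
        bzx = np.sqrt(weights) * se_zy  # w = bzx^2/se^2
        bzy = ratios * bzx
        wn = weights / weights.sum()
        s = np.cumsum(wn) - wn / 2  # (0.2, 0.45, 0.55, 0.7, 0.9)
        j = int(np.searchsorted(s, 0.5) - 1)
        oracle = ratios[j] + (ratios[j + 1] - ratios[j]) * \
            (0.5 - s[j]) / (s[j + 1] - s[j])
        assert oracle == pytest.approx(0.5)
        got = fit_weighted_median(bzx, bzy, np.full(5, se_zy))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_interpolates_between_bracketing_ratios(self):
        ratios = np.array([0.1, 0.5, 0.9])
        weights = np.array([2.0, 1.0, 2.0])
        se_zy = 0.1
        bzx = np.sqrt(weights) * se_zy
        bzy = ratios * bzx
        # s = (0.2, 0.5, 0.8) -> weight-0.5 quantile is the middle ratio
        assert fit_weighted_median(bzx, bzy, np.full(3, se_zy)) == \
            pytest.approx(0.5, rel=1e-12)


class TestWeightedMode:
    def test_point_mass(self):
        bzx = np.array([0.1, 0.2, 0.3])
        e = weighted_mode(make_hset(bzx, 0.3 * bzx, [0.01] * 3),
                          n_boot=300, seed=1)
        assert e.beta == pytest.approx(0.3, rel=1e-9)

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(8)
        cluster = 0.5 + rng.normal(0, 0.02, 7)
        outliers = 2.0 + rng.normal(0, 0.02, 3)
        ratios = np.concatenate([cluster, outliers])
        bzx = np.full(10, 0.5)
        bzy = ratios * bzx
        e = weighted_mode(make_hset(bzx, bzy, [0.02] * 10), n_boot=300, seed=2)
        assert 0.4 < e.beta < 0.6

    def test_reordering_invariance(self):
        rng = np.random.default_rng(12)
        bzx = np.abs(rng.normal(0.3, 0.1, 9))
        bzy = 0.4 * bzx + rng.normal(0, 0.02, 9)
        se_zy = rng.uniform(0.01, 0.04, 9)
        perm = rng.permutation(9)
        e1 = weighted_mode(make_hset(bzx, bzy, se_zy), n_boot=200, seed=3)
        e2 = weighted_mode(make_hset(bzx[perm], bzy[perm], se_zy[perm]),
                           n_boot=200, seed=3)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-9)


class TestMvIvw:
    def test_inert_covariate_recovers_single_exposure_effect(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(0.2, 0.05, 10)
        x2 = rng.normal(0.01, 0.005, 10)  # inert: no outcome pathway
        bzy = 0.4 * x1
        m = mv_set(np.column_stack([x1, x2]), bzy, np.full(10, 0.02))
        ests = mv_ivw(m)
        assert ests[0].beta == pytest.approx(0.4, abs=1e-10)
        assert ests[1].beta == pytest.approx(0.0, abs=1e-10)

    def test_single_column_fit_reduces_to_ivw(self):
        rng = np.random.default_rng(7)
        bzx = rng.normal(0.2, 0.05, 8)
        bzy = rng.normal(0.1, 0.03, 8)
        se_zy = rng.uniform(0.01, 0.04, 8)
        coef, _ = fit_mv_ivw(bzx[:, None], bzy, se_zy)
        beta, _, _ = fit_ivw(bzx, bzy, se_zy)
        assert coef[0] == pytest.approx(beta, rel=1e-10)

    def test_matches_generalized_least_squares_oracle(self):
        rng = np.random.default_rng(13)
        X = np.column_stack([rng.normal(0.2, 0.1, 12),
                             rng.normal(-0.1, 0.1, 12)])
        se_zy = rng.uniform(0.02, 0.05, 12)
        bzy = X @ np.array([0.3, -0.2]) + rng.normal(0, 0.01, 12)
        fit = sm.WLS(bzy, X, weights=1 / se_zy ** 2).fit()
        ests = mv_ivw(mv_set(X, bzy, se_zy))
        assert ests[0].beta == pytest.approx(fit.params[0], rel=1e-8)
        assert ests[1].beta == pytest.approx(fit.params[1], rel=1e-8)
        # recovery within the oracle's confidence radius
        for est, true in zip(ests, (0.3, -0.2)):
            assert abs(est.beta - true) < 3 * est.se + 0.05

    def test_duplicated_exposure_is_collinear(self):
        x = np.linspace(0.1, 0.5, 8)
        with pytest.raises(CollinearityError):
            mv_ivw(mv_set(np.column_stack([x, x]), 0.3 * x, np.full(8, 0.02)))

    def test_too_few_rows(self):
        with pytest.raises(InsufficientSnpsError):
            mv_ivw(mv_set(np.ones((3, 2)) + np.arange(6).reshape(3, 2),
                          np.ones(3), np.full(3, 0.1)))


class TestEquivariance:
    """Negating every SNP-outcome effect negates every causal estimate and
    leaves the analytic standard errors unchanged."""

    def _sets(self):
        rng = np.random.default_rng(21)
        bzx = np.abs(rng.normal(0.25, 0.08, 12))
        bzy = 0.4 * bzx + rng.normal(0, 0.03, 12)
        se_zy = rng.uniform(0.01, 0.05, 12)
        return (make_hset(bzx, bzy, se_zy, se_zx=np.full(12, 0.02)),
                make_hset(bzx, -bzy, se_zy, se_zx=np.full(12, 0.02)))

    def test_ivw_and_egger(self):
        h, hn = self._sets()
        a, b = ivw(h), ivw(hn)
        assert b.beta == pytest.approx(-a.beta, rel=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)
        ea, eb = egger(h), egger(hn)
        assert eb.beta == pytest.approx(-ea.beta, rel=1e-12)
        assert eb.se == pytest.approx(ea.se, rel=1e-12)
        assert eb.intercept == pytest.approx(-ea.intercept, rel=1e-12)

    def test_median_and_mode_point_estimates(self):
        h, hn = self._sets()
        assert fit_weighted_median(hn.beta_zx, hn.beta_zy, hn.se_zy) == \
            pytest.approx(-fit_weighted_median(h.beta_zx, h.beta_zy, h.se_zy),
                          rel=1e-10)
        from pleiomr.estimators import fit_weighted_mode
        assert fit_weighted_mode(hn.beta_zx, hn.beta_zy, hn.se_zy) == \
            pytest.approx(-fit_weighted_mode(h.beta_zx, h.beta_zy, h.se_zy),
                          abs=1e-6)

    def test_mv_ivw(self):
        rng = np.random.default_rng(22)
        X = np.column_stack([rng.normal(0.2, 0.1, 10),
                             rng.normal(0.1, 0.1, 10)])
        se_zy = rng.uniform(0.02, 0.05, 10)
        bzy = X @ np.array([0.3, -0.2]) + rng.normal(0, 0.01, 10)
        a = mv_ivw(mv_set(X, bzy, se_zy))
        b = mv_ivw(mv_set(X, -bzy, se_zy))
        for ea, eb in zip(a, b):
            assert eb.beta == pytest.approx(-ea.beta, rel=1e-12)
            assert eb.se == pytest.approx(ea.se, rel=1e-12)
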