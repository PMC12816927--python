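"""MR estimators: Wald ratio, IVW, Egger, Cochran's Q, PRESSO, leave-one-out."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrpv.instruments import HarmonizedInstrumentSet
from mrpv.mr import (
    MRAnalysis,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mr_presso,
    wald_ratio,
)


def _hset(b_exp, b_out, se_out, se_exp=None):
    b_exp = np.asarray(b_exp, float)
    se_exp = np.full_like(b_exp, 0.02) if se_exp is None else np.asarray(se_exp, float)
    return HarmonizedInstrumentSet.from_arrays(b_exp, se_exp, b_out, se_out)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.02, 0.0, 0.05).beta == 0.0

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(0.1, 0.02, 0.2, 0.05)
        b = wald_ratio(-0.1, 0.02, -0.2, 0.05)
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.2, 0.05)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        est = ivw(_hset([0.1], [0.2], [0.05]))
        ref = wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_equal_weight_mean(self):
        # identical exposure betas and outcome SEs -> plain mean of ratios
        est = ivw(_hset([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], [0.05] * 3), random_effects=False)
        assert est.beta == pytest.approx(2.0)

    def test_matches_weighted_zero_intercept_regression(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            k = int(rng.integers(3, 20))
            b_exp = rng.normal(0.3, 0.1, k)
            b_out = rng.normal(0.0, 0.02, k)
            se_out = rng.uniform(0.002, 0.01, k)
            est = ivw(_hset(b_exp, b_out, se_out), random_effects=False)
            wls = sm.WLS(b_out, b_exp[:, None], weights=1 / se_out**2).fit()
            assert est.beta == pytest.approx(wls.params[0], abs=1e-10)

    def test_or_scale_round_trip(self):
        est = ivw(_hset([0.2, 0.3], [0.02, 0.04], [0.005, 0.004]))
        lo, hi = est.or_ci
        assert np.log(est.or_) == pytest.approx(est.beta, abs=1e-12)
        assert np.log(lo) == pytest.approx(est.ci_low, abs=1e-12)
        assert np.log(hi) == pytest.approx(est.ci_high, abs=1e-12)

    def test_p_matches_normal_of_z(self):
        est = ivw(_hset([0.2, 0.3], [0.02, 0.04], [0.005, 0.004]))
        assert est.p == pytest.approx(2 * stats.norm.sf(abs(est.beta / est.se)), abs=1e-10)

    @given(st.lists(st.floats(0.5, 3.0), min_size=2, max_size=8))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_estimate_within_ratio_range(self, ratios):
        b_exp = np.full(len(ratios), 0.2)
        b_out = 0.2 * np.asarray(ratios)
        est = ivw(_hset(b_exp, b_out, np.full(len(ratios), 0.01)))
        assert min(ratios) - 1e-9 <= est.beta <= max(ratios) + 1e-9

    def test_allele_reorientation_invariance(self):
        b_exp = np.array([0.2, -0.3, 0.25, -0.15])
        b_out = np.array([0.02, -0.03, 0.02, -0.01])
        se_out = np.array([0.005, 0.004, 0.006, 0.005])
        flip = np.array([1, -1, -1, 1.0])
        a = ivw(_hset(b_exp, b_out, se_out))
        b = ivw(_hset(b_exp * flip, b_out * flip, se_out))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)
        qa = cochran_q(_hset(b_exp, b_out, se_out))
        qb = cochran_q(_hset(b_exp * flip, b_out * flip, se_out))
        assert qa[0] == pytest.approx(qb[0], abs=1e-12)
        ea, _ = egger(_hset(b_exp, b_out, se_out))
        eb, _ = egger(_hset(b_exp * flip, b_out * flip, se_out))
        assert ea.beta == pytest.approx(eb.beta, abs=1e-12)


class TestEgger:
    def test_recovers_line_with_intercept(self, rng):
        b_exp = np.linspace(0.1, 0.5, 12)
        b_out = 0.01 + 0.5 * b_exp + rng.normal(0, 1e-6, 12)
        slope, icept = egger(_hset(b_exp, b_out, np.full(12, 0.005)))
        assert slope.beta == pytest.approx(0.5, abs=1e-4)
        assert icept.intercept == pytest.approx(0.01, abs=1e-4)
        assert icept.df == 10

    def test_zero_intercept_fit_equals_fixed_effect_ivw(self, rng):
        b_exp = rng.normal(0.3, 0.1, 15)
        b_out = rng.normal(0.0, 0.02, 15)
        se_out = rng.uniform(0.002, 0.01, 15)
        fe = ivw(_hset(b_exp, b_out, se_out), random_effects=False)
        constrained, icept = egger(_hset(b_exp, b_out, se_out), fit_intercept=False)
        assert icept is None
        assert constrained.beta == pytest.approx(fe.beta, abs=1e-14)
        assert constrained.se == pytest.approx(fe.se, abs=1e-14)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            egger(_hset([0.1, 0.2], [0.01, 0.02], [0.005, 0.005]))


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        q, df, p = cochran_q(_hset([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], [0.01] * 3))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_snp_hand_computation(self):
        b_exp = np.array([0.2, 0.4])
        b_out = np.array([0.02, 0.08])
        se_out = np.array([0.01, 0.02])
        r = b_out / b_exp
        w = (b_exp / se_out) ** 2
        beta = (w * r).sum() / w.sum()
        expected = (w * (r - beta) ** 2).sum()
        q, df, p = cochran_q(_hset(b_exp, b_out, se_out))
        assert q == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)

    def test_homogeneous_simulation_mean_near_df(self, rng):
        qs = []
        for _ in range(300):
            b_exp = rng.uniform(0.2, 0.4, 10)
            se_out = np.full(10, 0.005)
            b_out = 0.1 * b_exp + rng.normal(0, se_out)
            q, df, _ = cochran_q(_hset(b_exp, b_out, se_out))
            qs.append(q / df)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.1)


class TestPresso:
    def _data(self, rng, outlier=None):
        k = 12
        b_exp = rng.uniform(0.2, 0.4, k)
        se_out = np.full(k, 0.005)
        b_out = 0.1 * b_exp + rng.normal(0, se_out)
        if outlier is not None:
            b_out[0] += outlier
        return _hset(b_exp, b_out, se_out)

    def test_deterministic_for_fixed_seed(self, rng):
        h = self._data(rng)
        a = mr_presso(h, n_sim=500, seed=3)
        b = mr_presso(h, n_sim=500, seed=3)
        assert a.global_p == b.global_p
        assert np.array_equal(a.outlier_p, b.outlier_p)

    def test_planted_outlier_flagged_and_corrected(self, rng):
        h = self._data(rng, outlier=10 * 0.005)
        res = mr_presso(h, n_sim=1000, seed=0)
        assert 0 in res.outlier_idx
        assert res.corrected is not None
        assert abs(res.corrected.beta - 0.1) < abs(ivw(h).beta - 0.1)

    def test_requires_four_instruments(self):
        with pytest.raises(ValueError):
            mr_presso(_hset([0.1] * 3, [0.01] * 3, [0.005] * 3))


class TestLeaveOneOut:
    def test_two_snps_each_equals_other_wald(self):
        h = _hset([0.1, 0.2], [0.05, 0.02], [0.01, 0.01])
        out = leave_one_out(h)
        assert out[0][1].beta == pytest.approx(wald_ratio(0.2, 0.02, 0.02, 0.01).beta)
        assert out[1][1].beta == pytest.approx(wald_ratio(0.1, 0.02, 0.05, 0.01).beta)

    def test_identical_instruments_all_equal(self):
        h = _hset([0.2] * 5, [0.04] * 5, [0.01] * 5)
        betas = {est.beta for _, est, _ in leave_one_out(h)}
        assert len(betas) == 1

    def test_dominant_outlier_flagged(self):
        b_exp = np.full(6, 0.2)
        b_out = np.array([0.02] * 5 + [0.2])
        h = _hset(b_exp, b_out, np.full(6, 0.001))
        flags = {snp: flag for snp, _, flag in leave_one_out(h, random_effects=False)}
        assert flags["snp5"]


def test_model_front_end_summary():
    rng = np.random.default_rng(0)
    b_exp = rng.uniform(0.2, 0.4, 10)
    se_out = np.full(10, 0.005)
    b_out = -0.1 * b_exp + rng.normal(0, se_out)
    fit = MRAnalysis(_hset(b_exp, b_out, se_out)).fit(presso=True, n_sim=200, seed=1)
    text = fit.summary()
    assert "ivw" in text and "Cochran" in text and "MR-PRESSO" in text
    assert fit.ivw.n_snps == 10
    frame = fit.to_frame()
    assert {"method", "or", "p"} <= set(frame.columns)
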