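"""Noncentral chi-square moments and the closed-form bias/risk expressions."""

import numpy as np
import pytest

from shrinkridge import (
    AsymptoticDesign,
    ValidationError,
    adb_all,
    aqdb_all,
    chi2_cdf,
    cov_all,
    inv_moment,
    mc_reference,
    risk_all,
)
from conftest import dominance_design, random_design


class TestChi2Cdf:
    def test_zero_and_central_closed_form(self):
        assert chi2_cdf(0.0, 3, 5.0) == 0.0
        for x in [0.5, 2.0, 7.0]:
            assert chi2_cdf(x, 2, 0.0) == pytest.approx(1 - np.exp(-x / 2),
                                                        abs=1e-12)

    def test_matches_monte_carlo(self, rng):
        v, delta, x = 5, 3.0, 7.0
        draws = (rng.standard_normal((10 ** 6, v))
                 + np.sqrt(delta / v)) ** 2  # sum of shifted squares
        emp = np.mean(draws.sum(axis=1) <= x)
        se = np.sqrt(emp * (1 - emp) / 10 ** 6)
        assert abs(chi2_cdf(x, v, delta) - emp) < 3 * se

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            chi2_cdf(-1.0, 3, 0.0)
        with pytest.raises(ValidationError):
            chi2_cdf(1.0, 0, 0.0)


class TestInvMoment:
    @pytest.mark.parametrize("j,v,expected", [
        (1, 5, 1 / 3), (1, 10, 1 / 8), (2, 7, 1 / 15), (2, 9, 1 / 35),
    ])
    def test_central_closed_forms(self, j, v, expected):
        assert inv_moment(j, v, 0.0) == pytest.approx(expected, abs=1e-8)

    def test_divergent_moment_rejected(self):
        with pytest.raises(ValidationError):
            inv_moment(1, 2, 0.0)

    def test_series_matches_quadrature(self):
        for args in [(1, 6, 2.0, None), (1, 6, 2.0, (4.0, "below")),
                     (2, 9, 5.0, (3.0, "above")), (1, 7, 0.0, (2.0, "below"))]:
            j, v, d, tr = args
            assert inv_moment(j, v, d, trunc=tr) == pytest.approx(
                inv_moment(j, v, d, trunc=tr, method="quad"), rel=1e-7)

    def test_truncated_matches_monte_carlo(self, rng):
        v, delta, c = 6, 2.0, 4.0
        nc = rng.noncentral_chisquare(v, delta, 10 ** 6)
        vals = (1.0 / nc) * (nc <= c)
        se = vals.std() / 1000.0
        assert abs(inv_moment(1, v, delta, trunc=(c, "below")) - vals.mean()) \
            < 3 * se

    def test_below_and_above_partition_the_moment(self):
        full = inv_moment(1, 8, 3.0)
        lo = inv_moment(1, 8, 3.0, trunc=(5.0, "below"))
        hi = inv_moment(1, 8, 3.0, trunc=(5.0, "above"))
        assert lo + hi == pytest.approx(full, rel=1e-10)


class TestBiasFormulas:
    def test_null_design_all_zero(self, rng):
        des = random_design(rng, delta=0.0)
        for b in adb_all(des).values():
            np.testing.assert_allclose(b, 0.0, atol=1e-12)
        for v in aqdb_all(des).values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_no_drift_fm_unbiased_sm_bias_is_delta(self, rng):
        des = random_design(rng, delta=2.0)
        adbs = adb_all(des)
        np.testing.assert_allclose(adbs["RFM"], 0.0, atol=1e-12)
        np.testing.assert_allclose(adbs["RSM"], -des.delta, atol=1e-12)

    def test_aqdb_is_quadratic_form_of_adb(self, rng):
        for delta in [0.5, 4.0]:
            des = random_design(rng, delta=delta)
            adbs, aqdbs = adb_all(des), aqdb_all(des)
            for name, b in adbs.items():
                assert aqdbs[name] == pytest.approx(
                    float(b @ des.B11_2 @ b), rel=1e-8, abs=1e-12)

    def test_pretest_aqdb_vanishes_for_large_delta(self, rng):
        des_small = random_design(rng, delta=1.0)
        des_big = AsymptoticDesign(des_small.B, des_small.p1,
                                   des_small.kappa * 40)
        assert aqdb_all(des_big)["RPT"] < 1e-6
        assert aqdb_all(des_big)["RPT"] < aqdb_all(des_small)["RPT"] + 1e-9


class TestRiskFormulas:
    def test_null_design_closed_forms_and_ordering(self, rng):
        des = random_design(rng, delta=0.0)
        risks = risk_all(des)
        B112_inv = np.linalg.inv(des.B11_2)
        assert risks["RFM"] == pytest.approx(np.trace(des.Q @ B112_inv),
                                             rel=1e-10)
        assert risks["RSM"] == pytest.approx(np.trace(des.Q @ des.B11_inv),
                                             rel=1e-10)
        assert risks["RSM"] <= risks["RFM"] + 1e-12

    def test_large_delta_risks_approach_full_model(self, rng):
        des = random_design(rng, delta=1.0)
        big = AsymptoticDesign(des.B, des.p1, des.kappa * 60)
        risks = risk_all(big)
        for name in ("RPT", "RSE", "RPS"):
            assert risks[name] == pytest.approx(risks["RFM"], rel=1e-3)

    def test_stein_dominance_over_delta_grid(self, rng):
        # RSE <= RFM on designs in the dominance domain; RPS <= RSE always;
        # RSM risk unbounded (monotone tail in Delta)
        for _ in range(5):
            des0 = dominance_design(rng)
            prev_sm = None
            for delta in np.arange(0.0, 10.1, 0.5):
                des = AsymptoticDesign(des0.B, des0.p1,
                                       _scaled_kappa(des0, delta))
                risks = risk_all(des)
                assert risks["RSE"] <= risks["RFM"] + 1e-10
                assert risks["RPS"] <= risks["RSE"] + 1e-10
                if delta >= 5.0:
                    assert prev_sm is None or risks["RSM"] > prev_sm - 1e-12
                    prev_sm = risks["RSM"]

    def test_positive_part_dominates_stein_on_generic_designs(self, rng):
        # RPS <= RSE needs no spectral condition
        for _ in range(5):
            des0 = random_design(rng, p1=3, p2=5)
            for delta in [0.0, 0.5, 2.0, 6.0]:
                des = AsymptoticDesign(des0.B, des0.p1,
                                       _scaled_kappa(des0, delta))
                risks = risk_all(des)
                assert risks["RPS"] <= risks["RSE"] + 1e-10

    def test_block_diagonal_B_collapses_all_risks(self, rng):
        p1, p2 = 3, 5
        A1 = rng.standard_normal((p1, p1))
        A2 = rng.standard_normal((p2, p2))
        B = np.zeros((p1 + p2, p1 + p2))
        B[:p1, :p1] = A1 @ A1.T + p1 * np.eye(p1)
        B[p1:, p1:] = A2 @ A2.T + p2 * np.eye(p2)
        des = AsymptoticDesign(B, p1, rng.standard_normal(p2))
        risks = risk_all(des)
        for name in ("RSM", "RPT", "RSE", "RPS"):
            assert risks[name] == pytest.approx(risks["RFM"], rel=1e-10)

    def test_formulas_match_sampling_oracle(self, rng):
        # moderate-draw cross-check; the full-scale version runs in the
        # acceptance suite
        des = random_design(rng, delta=2.0)
        ref = mc_reference(des, n_draws=200_000, rng=3)
        adbs, risks = adb_all(des), risk_all(des)
        covs = cov_all(des)
        for name in risks:
            assert abs(risks[name] - ref[name]["risk"]) \
                < 3 * ref[name]["risk_se"]
            np.testing.assert_array_less(
                np.abs(adbs[name] - ref[name]["adb"]),
                3 * ref[name]["adb_se"] + 1e-12)
            # risk is the Q-trace of the covariance
            assert risks[name] == pytest.approx(
                float(np.trace(des.Q @ covs[name])), rel=1e-12)


def _scaled_kappa(des, delta):
    if delta == 0:
        return np.zeros(des.p2)
    return des.kappa * np.sqrt(delta / des.noncentrality)
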