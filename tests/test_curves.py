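"""Digestion curve, detectability integral and observation likelihoods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import bernoulli

import molpred as mp
from molpred.curves import DigestionParams, PredationRate


class TestDetectionProbability:
    @pytest.mark.parametrize("beta0, beta1, t, expected", [
        (0.0, 1.0, 0.0, 0.5),          # logit^-1(0)
        (2.0, 0.1, 20.0, 0.5),         # exponent exactly zero
        (3.0, 0.05, 72.0, expit(-0.6)),  # ~0.3543
    ])
    def test_values(self, beta0, beta1, t, expected):
        assert mp.detection_probability(beta0, beta1, t) == pytest.approx(
            expected, rel=1e-12)

    @given(beta0=st.floats(-5, 5), beta1=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_time(self, beta0, beta1):
        t = np.linspace(0, 100, 40)
        p = mp.detection_probability(beta0, beta1, t)
        assert np.all(np.diff(p) < 0)
        assert np.all((p > 0) & (p < 1))

    def test_monotone_in_parameters(self):
        t = 10.0
        b0 = np.linspace(-3, 3, 10)
        assert np.all(np.diff(mp.detection_probability(b0, 0.1, t)) > 0)
        b1 = np.linspace(0.01, 2, 10)
        assert np.all(np.diff(mp.detection_probability(1.0, b1, t)) < 0)

    def test_extreme_exponents_stable(self):
        assert mp.detection_probability(700.0, 1.0, 0.0) == pytest.approx(1.0)
        assert mp.detection_probability(-700.0, 1.0, 0.0) == pytest.approx(0.0)
        assert np.isfinite(mp.detection_probability(0.0, 1.0, 700.0))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mp.detection_probability(0.0, 1.0, -1.0)
        with pytest.raises(ValueError):
            mp.detection_probability(0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            mp.detection_probability(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            DigestionParams(beta0=1.0, beta1=-0.1)


class TestDetectabilityIntegral:
    def test_unit_slope_gives_ln2(self):
        # independent oracle: numerical quadrature of logit^-1(-t)
        numeric, _ = quad(lambda t: expit(-t), 0, 60)
        assert mp.detectability_integral(0.0, 1.0) == pytest.approx(np.log(2))
        assert mp.detectability_integral(0.0, 1.0) == pytest.approx(
            numeric, rel=1e-9)

    def test_example_pair(self):
        numeric, _ = quad(lambda t: expit(2.0 - 0.1 * t), 0, 600, limit=200)
        closed = mp.detectability_integral(2.0, 0.1)
        assert closed == pytest.approx(21.269, abs=5e-4)
        assert closed == pytest.approx(numeric, rel=1e-9)

    def test_inverse_slope_scaling(self):
        assert mp.detectability_integral(1.3, 1.0) == pytest.approx(
            10.0 * mp.detectability_integral(1.3, 10.0))

    def test_large_beta0_stable(self):
        # for beta0 >> 0 the integral approaches beta0 / beta1
        assert mp.detectability_integral(600.0, 1.0) == pytest.approx(600.0)
        assert mp.detectability_integral(-600.0, 1.0) > 0

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            mp.detectability_integral(1.0, 0.0)


class TestFieldPositiveProbability:
    @pytest.mark.parametrize("lam, integral, expected", [
        (0.0, 21.269, 0.0),
        (np.log(2), 1.0, 0.5),
        (0.05, 21.269, 0.6547),
    ])
    def test_values(self, lam, integral, expected):
        assert mp.field_positive_probability(lam, integral) == pytest.approx(
            expected, abs=1e-4)

    def test_monotone_both_arguments(self):
        lams = np.linspace(0, 1, 20)
        assert np.all(np.diff(mp.field_positive_probability(lams, 5.0)) > 0)
        Is = np.linspace(0, 50, 20)
        assert np.all(np.diff(mp.field_positive_probability(0.1, Is)) > 0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mp.field_positive_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            mp.field_positive_probability(0.1, -1.0)
        with pytest.raises(ValueError):
            PredationRate(lam=-0.01)

    def test_daily_reporting_convention(self):
        assert PredationRate(lam=0.05).daily == pytest.approx(1.2)


def _lab_row(pred, prey, hours, detected):
    return {"predator_code": pred, "prey": prey,
            "hours_since_feeding": hours, "detected": detected}


class TestLabLoglik:
    def test_single_observation_at_half(self):
        params = {("c", "p"): DigestionParams(0.0, 1.0)}
        data = pd.DataFrame([_lab_row("c", "p", 0.0, 1)])
        assert mp.lab_loglik(data, params) == pytest.approx(np.log(0.5))
        data0 = pd.DataFrame([_lab_row("c", "p", 0.0, 0)])
        assert mp.lab_loglik(data0, params) == pytest.approx(np.log(0.5))

    def test_matches_rowwise_oracle(self, rng):
        params = {("c1", "p1"): DigestionParams(2.0, 0.1),
                  ("c2", "p1"): DigestionParams(-0.5, 0.05)}
        rows = []
        for _ in range(8):
            pred = rng.choice(["c1", "c2"])
            rows.append(_lab_row(pred, "p1", float(rng.uniform(0, 72)),
                                 int(rng.integers(2))))
        data = pd.DataFrame(rows)
        # brute-force per-row sum with scipy's Bernoulli pmf
        expected = sum(
            bernoulli.logpmf(r["detected"],
                             params[(r["predator_code"], "p1")].pi(
                                 r["hours_since_feeding"]))
            for _, r in data.iterrows())
        assert mp.lab_loglik(data, params) == pytest.approx(expected)

    def test_unknown_pair_raises(self):
        data = pd.DataFrame([_lab_row("nobody", "p", 1.0, 1)])
        with pytest.raises(KeyError):
            mp.lab_loglik(data, {("c", "p"): DigestionParams(0.0, 1.0)})


def _field_row(ind, pred, prey, detected):
    return {"individual_id": ind, "predator_code": pred, "prey": prey,
            "detected": detected}


class TestFieldLoglik:
    def test_all_negative_with_zero_rate(self):
        data = pd.DataFrame([_field_row(f"i{k}", "c", "p", 0)
                             for k in range(10)])
        ll = mp.field_loglik(data, {("c", "p"): PredationRate(0.0)},
                             {("c", "p"): 20.0})
        assert ll == pytest.approx(0.0)

    def test_single_positive_at_half(self):
        data = pd.DataFrame([_field_row("i1", "c", "p", 1)])
        ll = mp.field_loglik(data, {("c", "p"): PredationRate(np.log(2))},
                             {("c", "p"): 1.0})
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_rowwise_oracle(self, rng):
        lam = {("c1", "p"): PredationRate(0.04), ("c2", "p"): PredationRate(0.01)}
        I = {("c1", "p"): 21.3, ("c2", "p"): 12.0}
        rows = [_field_row(f"i{k}", rng.choice(["c1", "c2"]), "p",
                           int(rng.integers(2))) for k in range(10)]
        data = pd.DataFrame(rows)
        expected = sum(
            bernoulli.logpmf(
                r["detected"],
                -np.expm1(-lam[(r["predator_code"], "p")].lam
                          * I[(r["predator_code"], "p")]))
            for _, r in data.iterrows())
        assert mp.field_loglik(data, lam, I) == pytest.approx(expected)

    def test_unknown_pair_raises(self):
        data = pd.DataFrame([_field_row("i1", "x", "p", 1)])
        with pytest.raises(KeyError):
            mp.field_loglik(data, {("c", "p"): PredationRate(0.1)},
                            {("c", "p"): 10.0})
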