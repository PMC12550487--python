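"""Model construction, posterior computation, diagnostics and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfnorm

import molpred as mp
from molpred.model import gelman_rubin


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, tiny_data):
        lab, field = tiny_data
        m = mp.PredationModel(lab, field)
        rng = np.random.default_rng(3)
        for _ in range(2):
            theta = rng.normal(0, 0.4, m.n_params)
            lp, grad = m.logpost_and_grad(theta)
            assert np.isfinite(lp)
            eps = 1e-6
            for j in rng.choice(m.n_params, size=12, replace=False):
                e = np.zeros(m.n_params)
                e[j] = eps
                fd = (m.logpost_and_grad(theta + e)[0]
                      - m.logpost_and_grad(theta - e)[0]) / (2 * eps)
                assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_interweave_preserves_effects_and_density_terms(self, tiny_data):
        lab, field = tiny_data
        m = mp.PredationModel(lab, field)
        rng = np.random.default_rng(4)
        theta = rng.normal(0, 0.3, m.n_params)
        theta2 = m._gibbs_interweave(theta, rng)
        # likelihood-relevant quantities are invariant under the update
        b0_a = m._unpack(theta)[-3]
        ll_a = m._unpack(theta)[-2]
        b0_b = m._unpack(theta2)[-3]
        ll_b = m._unpack(theta2)[-2]
        assert np.allclose(b0_a, b0_b)
        assert np.allclose(ll_a, ll_b)
        lp2, _ = m.logpost_and_grad(theta2)
        assert np.isfinite(lp2)

    def test_never_nan_on_extreme_points(self, tiny_data):
        lab, field = tiny_data
        m = mp.PredationModel(lab, field)
        for scale in (1.0, 10.0, 100.0):
            theta = np.full(m.n_params, scale)
            lp, grad = m.logpost_and_grad(theta)
            assert not np.isnan(lp)
            assert not np.any(np.isnan(grad))

    def test_empty_inputs_rejected(self, tiny_data):
        lab, field = tiny_data
        with pytest.raises(ValueError):
            mp.PredationModel(lab.iloc[:0], field)
        with pytest.raises(ValueError):
            mp.PredationModel(lab, field.iloc[:0])


class TestGelmanRubin:
    def test_identical_chains_below_one(self):
        chain = np.random.default_rng(0).normal(size=200)
        assert gelman_rubin(np.stack([chain, chain])) < 1.0

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 5000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 500))
        chains[1] += 5.0
        assert gelman_rubin(chains) > 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestFit:
    def test_single_pair_recovery(self, single_pair_fit):
        scn, lab, field, res = single_pair_fit
        true_daily = 24 * 0.05
        summ = res.daily_rate_summary(quantiles=(0.05, 0.95))
        median = summ["median"].iloc[0]
        assert abs(median - true_daily) / true_daily < 0.25
        assert summ["q0.05"].iloc[0] <= true_daily <= summ["q0.95"].iloc[0]

    def test_digestion_curve_recovery(self, single_pair_fit):
        scn, lab, field, res = single_pair_fit
        dig = res.digestion_summary(quantiles=(0.005, 0.995))
        assert dig["beta0_q0.005"].iloc[0] <= 2.0 <= dig["beta0_q0.995"].iloc[0]
        assert dig["beta1_q0.005"].iloc[0] <= 0.1 <= dig["beta1_q0.995"].iloc[0]

    def test_zero_rate_data_concentrates_near_zero(self, rng):
        scn = mp.SimulationScenario(
            prey=("p",), predators=("c",),
            beta0=np.array([[2.0]]), beta1=np.array([[0.1]]),
            lam=np.array([[0.0]]), field_n=np.array([300]),
            lab_times=(2.0, 8.0, 24.0, 48.0), lab_n=10, seed=2)
        lab = mp.simulate_feeding_trial(scn)
        field = mp.simulate_field_tests(scn)
        assert field["detected"].sum() == 0
        res = mp.PredationModel(lab, field).fit(
            draws=400, warmup=400, chains=2, seed=3)
        post_q95 = np.quantile(res.posterior["daily_rate"], 0.95)
        # independent prior oracle: daily rate under the prior alone
        n = 20000
        mu = rng.normal(0, 1, n)
        sd = halfnorm.rvs(scale=1, size=(2, n), random_state=1)
        lnlam = (rng.normal(0, 2, n) + mu + sd[0] * rng.normal(size=n)
                 + sd[1] * rng.normal(size=n))
        prior_q95 = np.quantile(24 * np.exp(lnlam), 0.95)
        assert post_q95 < prior_q95

    def test_all_positive_field_warns_saturation(self):
        lab = pd.DataFrame({"predator_code": ["c"] * 4, "prey": ["p"] * 4,
                            "hours_since_feeding": [2.0, 8.0, 24.0, 48.0],
                            "detected": [1, 1, 0, 0]})
        field = pd.DataFrame({"individual_id": [f"i{k}" for k in range(5)],
                              "predator_code": ["c"] * 5, "prey": ["p"] * 5,
                              "detected": [1] * 5})
        model = mp.PredationModel(lab, field)
        with pytest.warns(mp.SaturationWarning):
            model.fit(draws=20, warmup=20, chains=2, seed=0)

    def test_seeded_fits_identical(self, tiny_data):
        lab, field = tiny_data
        m = mp.PredationModel(lab, field)
        r1 = m.fit(draws=60, warmup=60, chains=2, seed=5)
        r2 = m.fit(draws=60, warmup=60, chains=2, seed=5)
        for key in r1.posterior:
            assert np.array_equal(r1.posterior[key], r2.posterior[key])

    def test_emcee_agrees_on_single_pair_posterior(self, single_pair_fit):
        """Independent MCMC cross-check with emcee's ensemble sampler."""
        emcee = pytest.importorskip("emcee")
        scn, lab, field, res = single_pair_fit
        m = mp.PredationModel(lab, field)
        nwalkers, ndim = 64, m.n_params
        rng = np.random.default_rng(8)
        p0 = rng.normal(0, 0.2, (nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, lambda th: m.logpost_and_grad(th)[0])
        sampler.random_state = np.random.RandomState(9).get_state()
        sampler.run_mcmc(p0, 2500, progress=False)
        chain = sampler.get_chain(discard=1200, flat=True)
        post = m._constrain(chain[None, ...])
        ref = res.posterior["daily_rate"].ravel()
        alt = post["daily_rate"].ravel()
        assert np.median(alt) == pytest.approx(np.median(ref), rel=0.10)
        assert alt.std() == pytest.approx(ref.std(), rel=0.35)


class TestSummaries:
    def _constant_results(self, value=2.0):
        reg = mp.Registry(prey=("p",), predators=("c",))
        shape = (2, 50, 1, 1)
        post = {"daily_rate": np.full(shape, value),
                "lam": np.full(shape, value / 24),
                "beta0": np.full(shape, 1.0), "beta1": np.full(shape, 0.1),
                "detectability": np.full(shape, 13.1),
                "p_detect": np.full(shape, 0.5)}
        return mp.PredationResults(reg, post, settings={})

    def test_constant_draws(self):
        res = self._constant_results(2.0)
        summ = res.daily_rate_summary()
        assert summ["median"].iloc[0] == 2.0
        assert summ["mean"].iloc[0] == 2.0
        assert summ["sd"].iloc[0] == 0.0

    def test_lower_interpolation_quantile_convention(self):
        res = self._constant_results()
        draws = np.array([24.0, 24.0 * np.e])
        res.posterior["daily_rate"] = draws.reshape(1, 2, 1, 1)
        summ = res.daily_rate_summary()
        # lower interpolation: the reported median is an actual draw
        assert summ["median"].iloc[0] == 24.0

    def test_summaries_match_raw_draw_recomputation(self, single_pair_fit):
        *_, res = single_pair_fit
        summ = res.daily_rate_summary(quantiles=(0.25, 0.75))
        raw = res.posterior["daily_rate"].ravel()
        assert summ["mean"].iloc[0] == pytest.approx(raw.mean())
        assert summ["sd"].iloc[0] == pytest.approx(raw.std(ddof=1))
        assert summ["q0.25"].iloc[0] == np.quantile(raw, 0.25, method="lower")
        assert summ["median"].iloc[0] == np.quantile(raw, 0.5, method="lower")

    def test_fit_report_renders(self, single_pair_fit):
        *_, res = single_pair_fit
        text = str(res.summary())
        assert "Daily predation rates" in text
        assert "PSRF" in text


class TestPosteriorPredictiveCheck:
    def test_intervals_and_degenerate_frequency(self, single_pair_fit):
        scn, lab, field, res = single_pair_fit
        one_obs = pd.concat([
            field,
            pd.DataFrame({"individual_id": ["solo"],
                          "predator_code": ["PoCu"],
                          "prey": ["springtail"], "detected": [1]})])
        ppc = res.posterior_predictive_check(field)
        assert set(ppc.columns) >= {"observed_freq", "q2.5", "q97.5",
                                    "inside_95", "inside_50"}
        assert (ppc["q2.5"] <= ppc["q25"]).all()
        assert (ppc["q75"] <= ppc["q97.5"]).all()
        # a single-observation species yields frequency 0 or 1
        solo = pd.DataFrame({"individual_id": ["solo"],
                             "predator_code": ["PoCu"],
                             "prey": ["springtail"], "detected": [1]})
        ppc_solo = res.posterior_predictive_check(solo)
        assert ppc_solo["observed_freq"].iloc[0] in (0.0, 1.0)

    def test_calibrated_fit_covers_observed_frequency(self, single_pair_fit):
        scn, lab, field, res = single_pair_fit
        ppc = res.posterior_predictive_check(field)
        assert ppc.attrs["fraction_inside_95"] == 1.0


class TestPersistence:
    def test_save_load_roundtrip(self, single_pair_fit, tmp_path):
        *_, res = single_pair_fit
        res.save(tmp_path / "draws.npz")
        back = mp.PredationResults.load(tmp_path / "draws.npz")
        assert back.registry == res.registry
        for key in res.posterior:
            assert np.array_equal(back.posterior[key], res.posterior[key])

    def test_inference_data_coords(self, single_pair_fit):
        *_, res = single_pair_fit
        idata = res.to_inference_data()
        assert list(idata.posterior["daily_rate"].dims) == \
            ["chain", "draw", "prey", "predator"]
        assert list(idata.posterior.coords["predator"].values) == ["PoCu"]
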