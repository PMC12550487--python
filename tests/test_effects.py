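"""Effect decomposition, registries and the hierarchical prior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import halfnorm, norm

import molpred as mp
from molpred.effects import FamilyPrior


@pytest.fixture
def registry():
    return mp.Registry(prey=tuple(f"p{i}" for i in range(5)),
                       predators=tuple(f"c{j}" for j in range(25)))


def random_effects(registry, rng):
    P, C = registry.n_prey, registry.n_predators
    return mp.EffectDecomposition(
        registry,
        alpha_beta0=rng.normal(size=P), delta_beta0=rng.normal(size=C),
        gamma_beta0=rng.normal(size=(P, C)),
        alpha_lam=rng.normal(size=P), delta_lam=rng.normal(size=C),
        gamma_lam=rng.normal(size=(P, C)),
        log_beta1=rng.normal(size=(P, C)))


class TestRegistry:
    def test_union_from_both_datasets(self, tiny_data):
        lab, field = tiny_data
        extra = lab.copy()
        extra.loc[extra.index[-1], "predator_code"] = "LABONLY"
        reg = mp.Registry.from_data(extra, field)
        assert "LABONLY" in reg.predators  # retained: hierarchy fills the gap
        assert set(reg.prey) == {"aphid", "slug"}

    def test_duplicate_and_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            mp.Registry(prey=("a", "a"), predators=("x",))
        with pytest.raises(ValueError):
            mp.Registry(prey=(), predators=("x",))

    def test_unknown_label(self, registry):
        with pytest.raises(KeyError):
            registry.prey_index("nope")
        with pytest.raises(KeyError):
            registry.predator_index("nope")


class TestAssembly:
    def test_zero_effects(self, registry, rng):
        eff = random_effects(registry, rng)
        eff.alpha_beta0[:] = 0
        eff.delta_beta0[:] = 0
        eff.gamma_beta0[:] = 0
        assert mp.assemble_beta0(eff, "p0", "c0") == 0.0

    def test_arithmetic(self, registry, rng):
        eff = random_effects(registry, rng)
        eff.alpha_beta0[0] = 1.5
        eff.delta_beta0[0] = -0.5
        eff.gamma_beta0[0, 0] = 0.2
        assert mp.assemble_beta0(eff, "p0", "c0") == pytest.approx(1.2)
        eff.alpha_lam[1] = -3.0
        eff.delta_lam[2] = -1.0
        eff.gamma_lam[1, 2] = 0.0
        lam = np.exp(mp.assemble_log_lambda(eff, "p1", "c2"))
        assert lam == pytest.approx(np.exp(-4.0))

    def test_full_grid_matches_elementwise_oracle(self, registry, rng):
        eff = random_effects(registry, rng)
        grid_b0 = eff.beta0()
        grid_ll = eff.log_lambda()
        for ip, p in enumerate(registry.prey):
            for ic, c in enumerate(registry.predators):
                # brute-force recomputation per element
                assert grid_b0[ip, ic] == pytest.approx(
                    eff.alpha_beta0[ip] + eff.delta_beta0[ic]
                    + eff.gamma_beta0[ip, ic])
                assert grid_ll[ip, ic] == pytest.approx(
                    mp.assemble_log_lambda(eff, p, c))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_positivity_for_any_finite_effects(self, seed):
        reg = mp.Registry(prey=("a", "b"), predators=("x", "y", "z"))
        eff = random_effects(reg, np.random.default_rng(seed))
        eff.log_beta1 *= 10  # push to extremes
        assert np.all(eff.lam() > 0)
        assert np.all(eff.beta1() > 0)

    def test_shape_validation(self, registry, rng):
        with pytest.raises(ValueError):
            mp.EffectDecomposition(
                registry, alpha_beta0=np.zeros(3),  # wrong length
                delta_beta0=np.zeros(25), gamma_beta0=np.zeros((5, 25)),
                alpha_lam=np.zeros(5), delta_lam=np.zeros(25),
                gamma_lam=np.zeros((5, 25)), log_beta1=np.zeros((5, 25)))


class TestPriorLogdensity:
    def test_closed_form_at_modes(self):
        reg = mp.Registry(prey=("a",), predators=("x", "y"))
        P, C = 1, 2
        eff = mp.EffectDecomposition(
            reg, *(np.zeros(s) for s in (P, C, (P, C), P, C, (P, C), (P, C))))
        hyper = mp.Hyperparameters()  # all locations 0, scales 1
        got = mp.prior_logdensity(eff, hyper)
        # analytic: every effect term is a Normal(0|loc, scale) density
        expected = (
            2 * P * norm.logpdf(0, 0, 2)        # prey effects, fixed N(0,2)
            + 2 * C * norm.logpdf(0, 0, 1)      # predator effects
            + 3 * P * C * norm.logpdf(0, 0, 1)  # interactions + log-slopes
            + 3 * norm.logpdf(0, 0, 1)          # location hyperpriors
            + 5 * halfnorm.logpdf(1, scale=1))  # scale hyperpriors
        assert got == pytest.approx(expected)

    def test_doubling_one_scale_touches_one_family(self, registry, rng):
        eff = random_effects(registry, rng)
        h1 = mp.Hyperparameters()
        h2 = mp.Hyperparameters(sigma_interaction_beta0=2.0)
        delta = mp.prior_logdensity(eff, h2) - mp.prior_logdensity(eff, h1)
        family_delta = (
            np.sum(norm.logpdf(eff.gamma_beta0, 0, 2.0))
            - np.sum(norm.logpdf(eff.gamma_beta0, 0, 1.0))
            + halfnorm.logpdf(2.0, scale=1) - halfnorm.logpdf(1.0, scale=1))
        assert delta == pytest.approx(family_delta)

    def test_matches_term_by_term_oracle(self, registry, rng):
        eff = random_effects(registry, rng)
        hyper = mp.Hyperparameters(
            mu_predator_beta0=0.3, sigma_predator_beta0=1.4,
            mu_predator_log_lambda=-0.2, sigma_predator_log_lambda=0.7,
            sigma_interaction_beta0=0.5, sigma_interaction_log_lambda=1.1,
            mu_log_beta1=-2.0, sigma_log_beta1=0.8)
        hp = mp.HyperPriors()
        expected = 0.0
        for x in eff.alpha_beta0:
            expected += norm.logpdf(x, hp.prey_beta0_loc, hp.prey_beta0_scale)
        for x in eff.alpha_lam:
            expected += norm.logpdf(x, 0, 2)
        for x in eff.delta_beta0:
            expected += norm.logpdf(x, 0.3, 1.4)
        for x in eff.delta_lam:
            expected += norm.logpdf(x, -0.2, 0.7)
        for x in eff.gamma_beta0.ravel():
            expected += norm.logpdf(x, 0, 0.5)
        for x in eff.gamma_lam.ravel():
            expected += norm.logpdf(x, 0, 1.1)
        for x in eff.log_beta1.ravel():
            expected += norm.logpdf(x, -2.0, 0.8)
        expected += norm.logpdf(0.3, 0, 1) + norm.logpdf(-0.2, 0, 1) \
            + norm.logpdf(-2.0, 0, 1)
        for s in (1.4, 0.7, 0.5, 1.1, 0.8):
            expected += halfnorm.logpdf(s, scale=1)
        assert mp.prior_logdensity(eff, hyper) == pytest.approx(expected)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            mp.Hyperparameters(sigma_log_beta1=0.0)
        with pytest.raises(ValueError):
            FamilyPrior(sigma_scale=-1.0)


class TestHyperPriorsConfig:
    def test_roundtrip_and_pinned_interactions(self):
        hp = mp.HyperPriors()
        d = hp.to_dict()
        assert "mu_loc" not in d["interaction_beta0"]  # location pinned at 0
        hp2 = mp.HyperPriors.from_dict(d)
        assert hp2 == hp
        custom = mp.HyperPriors.from_dict(
            {"prey_beta0": {"loc": 1.0, "scale": 3.0},
             "log_beta1": {"mu_loc": -2.0, "sigma_scale": 0.5}})
        assert custom.prey_beta0_scale == 3.0
        assert custom.log_beta1.mu_loc == -2.0
        assert custom.interaction_log_lambda.mu_fixed
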