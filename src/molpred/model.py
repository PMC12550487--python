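"""Joint hierarchical Bayesian model of predation and digestion.

:class:`PredationModel` binds a laboratory feeding-trial table and a
field-capture table to the process model: logistic DNA decay per
predator--prey pair, homogeneous Poisson predation, Bernoulli
observation models on both datasets, and the additive effect
decomposition with group-level hyperpriors.  :meth:`PredationModel.fit`
runs gradient-based MCMC (HMC, non-centred parameterization) and
returns a :class:`PredationResults` carrying posterior draws,
convergence diagnostics, summaries and the posterior-predictive
goodness-of-fit check.

The sampled parameter vector is fully unconstrained: scales enter as
logs (with the half-Normal prior Jacobian) and hierarchized effects as
standard-Normal offsets, which avoids funnel pathologies when data are
sparse.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import hmc
from .curves import HOURS_PER_DAY
from .effects import HyperPriors, Registry
from .io import validate_field, validate_lab

__all__ = [
    "PredationModel",
    "PredationResults",
    "FitReport",
    "SaturationWarning",
    "fit_model",
    "gelman_rubin",
]

logger = logging.getLogger("molpred")

#: Quantile interpolation convention used in all posterior summaries.
QUANTILE_METHOD = "lower"


class SaturationWarning(UserWarning):
    """All field tests positive: the detection channel is saturated.

    With no negative outcomes the likelihood cannot separate a large
    predation rate from an infinite one; estimates rely on the prior.
    """


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic Gelman--Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_iterations).  Uses the original
    between/within variance ratio (no rank normalization, no chain
    splitting); identical chains give sqrt((n-1)/n) < 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_iterations) array")
    m, n = chains.shape
    if n < 4:
        raise ValueError("need at least 4 iterations per chain")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class PredationModel:
    """Hierarchical model of per-pair predation rates and digestion curves.

    Parameters
    ----------
    lab : DataFrame
        Feeding-trial table (``predator_code, prey, hours_since_feeding,
        detected``); calibrates the digestion curves.
    field : DataFrame
        Field-capture table (``individual_id, predator_code, prey,
        detected``); identifies the predation rates.
    hyperpriors : HyperPriors, optional
        Prior constants; defaults are weakly informative.
    registry : Registry, optional
        Label registry; defaults to the union of labels in both tables.

    Examples
    --------
    >>> model = PredationModel.from_csv("lab.csv", "field.csv")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        lab: pd.DataFrame,
        field: pd.DataFrame,
        hyperpriors: Optional[HyperPriors] = None,
        registry: Optional[Registry] = None,
    ):
        lab = validate_lab(lab)
        field = validate_field(field)
        if not len(lab):
            raise ValueError("feeding-trial table is empty")
        if not len(field):
            raise ValueError("field table is empty")
        self.lab = lab
        self.field = field
        self.hyperpriors = hyperpriors or HyperPriors()
        self.registry = registry or Registry.from_data(lab, field)

        P, C = self.registry.n_prey, self.registry.n_predators
        prey_idx = {p: i for i, p in enumerate(self.registry.prey)}
        pred_idx = {c: i for i, c in enumerate(self.registry.predators)}

        def pair_of(df):
            try:
                ip = df["prey"].map(prey_idx).to_numpy()
                ic = df["predator_code"].map(pred_idx).to_numpy()
            except KeyError:  # pragma: no cover - map never raises
                raise
            if np.any(pd.isna(ip)) or np.any(pd.isna(ic)):
                bad = df.loc[pd.isna(ip) | pd.isna(ic),
                             ["predator_code", "prey"]].iloc[0]
                raise KeyError(
                    f"pair ({bad['predator_code']!r}, {bad['prey']!r}) "
                    "is not in the registry")
            return (ip.astype(int) * C + ic.astype(int))

        # aggregate to sufficient statistics: (pair, time) cells for the
        # lab, pair cells for the field
        lab_cells = (
            lab.assign(_pair=pair_of(lab))
            .groupby(["_pair", "hours_since_feeding"])["detected"]
            .agg(["count", "sum"])
            .reset_index()
        )
        self._lab_pair = lab_cells["_pair"].to_numpy(dtype=int)
        self._lab_t = lab_cells["hours_since_feeding"].to_numpy(dtype=float)
        self._lab_n = lab_cells["count"].to_numpy(dtype=float)
        self._lab_k = lab_cells["sum"].to_numpy(dtype=float)

        field_cells = (
            field.assign(_pair=pair_of(field))
            .groupby("_pair")["detected"]
            .agg(["count", "sum"])
            .reset_index()
        )
        self._field_pair = field_cells["_pair"].to_numpy(dtype=int)
        self._field_n = field_cells["count"].to_numpy(dtype=float)
        self._field_k = field_cells["sum"].to_numpy(dtype=float)

        # flattened pair -> (prey, predator) index maps
        self._prey_of_pair = np.repeat(np.arange(P), C)
        self._pred_of_pair = np.tile(np.arange(C), P)

        # parameter packing offsets
        self._P, self._C, self._K = P, C, P * C
        o = 2 * P
        self._sl_a0 = slice(0, P)
        self._sl_al = slice(P, 2 * P)
        self._i_mu_d0, self._i_mu_dl, self._i_mu_b1 = o, o + 1, o + 2
        self._sl_ls = slice(o + 3, o + 8)  # ls_d0, ls_dl, ls_g0, ls_gl, ls_b1
        o += 8
        self._sl_zd0 = slice(o, o + C)
        self._sl_zdl = slice(o + C, o + 2 * C)
        o += 2 * C
        self._sl_zg0 = slice(o, o + P * C)
        self._sl_zgl = slice(o + P * C, o + 2 * P * C)
        self._sl_zb1 = slice(o + 2 * P * C, o + 3 * P * C)
        self.n_params = o + 3 * P * C
        self._sl_z_all = slice(2 * P + 8, self.n_params)

        hp = self.hyperpriors
        self._fnk = self._field_n - self._field_k
        self._sig_scales = np.array([
            hp.predator_beta0.sigma_scale,
            hp.predator_log_lambda.sigma_scale,
            hp.interaction_beta0.sigma_scale,
            hp.interaction_log_lambda.sigma_scale,
            hp.log_beta1.sigma_scale,
        ])
        self._hp_vec = np.array([
            hp.prey_beta0_loc, hp.prey_beta0_scale,
            hp.prey_log_lambda_loc, hp.prey_log_lambda_scale,
            hp.predator_beta0.mu_loc, hp.predator_beta0.mu_scale,
            hp.predator_log_lambda.mu_loc, hp.predator_log_lambda.mu_scale,
            hp.log_beta1.mu_loc, hp.log_beta1.mu_scale,
            *self._sig_scales,
        ])
        try:
            from ._fastpost import nb_logpost_grad
            self._nb_kernel = nb_logpost_grad
        except ImportError:  # pragma: no cover - numba is a soft dependency
            self._nb_kernel = None

    @classmethod
    def from_csv(cls, lab_path, field_path, hyperpriors=None, **kwargs) -> "PredationModel":
        from .io import read_field, read_lab

        return cls(read_lab(lab_path), read_field(field_path, **kwargs),
                   hyperpriors=hyperpriors)

    # -- log posterior and gradient (unconstrained space) --------------

    def _unpack(self, theta: np.ndarray):
        """Map the sampled vector to effect values (non-centred)."""
        a0 = theta[self._sl_a0]
        al = theta[self._sl_al]
        mu_d0 = theta[self._i_mu_d0]
        mu_dl = theta[self._i_mu_dl]
        mu_b1 = theta[self._i_mu_b1]
        sig = np.exp(theta[self._sl_ls])  # s_d0, s_dl, s_g0, s_gl, s_b1
        z_d0 = theta[self._sl_zd0]
        z_dl = theta[self._sl_zdl]
        z_g0 = theta[self._sl_zg0]
        z_gl = theta[self._sl_zgl]
        z_b1 = theta[self._sl_zb1]
        d0 = mu_d0 + sig[0] * z_d0
        dl = mu_dl + sig[1] * z_dl
        lb1 = mu_b1 + sig[4] * z_b1
        b0 = a0[self._prey_of_pair] + d0[self._pred_of_pair] + sig[2] * z_g0
        ll = al[self._prey_of_pair] + dl[self._pred_of_pair] + sig[3] * z_gl
        return (a0, al, mu_d0, mu_dl, mu_b1, sig,
                z_d0, z_dl, z_g0, z_gl, z_b1, d0, dl, b0, ll, lb1)

    def logpost_and_grad(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        """Joint log posterior density and its gradient.

        Returns ``(-inf, 0)`` outside the numerically representable
        region; the sampler treats that as a divergence.  Dispatches to
        the compiled kernel when numba is available; the numpy
        reference path computes the same quantities.
        """
        if self._nb_kernel is not None:
            return self._nb_kernel(
                theta, self._P, self._C,
                self._lab_pair, self._lab_t, self._lab_n, self._lab_k,
                self._field_pair, self._field_n, self._field_k,
                self._hp_vec)
        return self._logpost_grad_numpy(theta)

    def _logpost_grad_numpy(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        """Reference implementation (pure numpy)."""
        hp = self.hyperpriors
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 300.0):
            return -np.inf, np.zeros_like(theta)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            (a0, al, mu_d0, mu_dl, mu_b1, sig,
             z_d0, z_dl, z_g0, z_gl, z_b1, d0, dl, b0, ll, lb1) = \
                self._unpack(theta)
            K = self._K
            beta1 = np.exp(lb1)
            lam = np.exp(ll)

            # laboratory likelihood: Bernoulli-logit
            eta = b0[self._lab_pair] - beta1[self._lab_pair] * self._lab_t
            lp = self._lab_k @ eta - self._lab_n @ np.logaddexp(0.0, eta)

            # field likelihood: p = 1 - exp(-lam * I)
            integral = np.logaddexp(0.0, b0) / beta1
            fp = self._field_pair
            m = np.minimum(lam[fp] * integral[fp], 700.0)
            log_p = np.log(-np.expm1(-m))
            lp += self._field_k @ log_p - self._fnk @ m

            # priors (constants dropped): fixed Normals for prey effects
            # and locations, standard Normals for every offset,
            # half-Normal + log-Jacobian for the scales
            ra = a0 - hp.prey_beta0_loc
            rl = al - hp.prey_log_lambda_loc
            z = theta[self._sl_z_all]
            ls = theta[self._sl_ls]
            sr = sig / self._sig_scales
            lp += (-0.5 * ((ra @ ra) / hp.prey_beta0_scale ** 2
                           + (rl @ rl) / hp.prey_log_lambda_scale ** 2
                           + z @ z
                           + ((mu_d0 - hp.predator_beta0.mu_loc)
                              / hp.predator_beta0.mu_scale) ** 2
                           + ((mu_dl - hp.predator_log_lambda.mu_loc)
                              / hp.predator_log_lambda.mu_scale) ** 2
                           + ((mu_b1 - hp.log_beta1.mu_loc)
                              / hp.log_beta1.mu_scale) ** 2
                           + sr @ sr)
                   + ls.sum())
            if not np.isfinite(lp):
                return -np.inf, np.zeros_like(theta)

            # ---- gradient ----------------------------------------------
            u = self._lab_k - self._lab_n * expit(eta)      # d lp / d eta
            g_b0 = np.bincount(self._lab_pair, weights=u, minlength=K)
            g_lb1 = np.bincount(self._lab_pair, weights=u * self._lab_t,
                                minlength=K) * (-beta1)

            em1 = np.maximum(np.expm1(m), 1e-300)
            w = self._field_k / em1 - self._fnk             # d lp / d m
            g_llf = np.bincount(fp, weights=w * m, minlength=K)
            g_b0 += np.bincount(fp, weights=w * lam[fp] * expit(b0[fp])
                                / beta1[fp], minlength=K)
            g_lb1 -= g_llf
            if not (np.isfinite(g_b0).all() and np.isfinite(g_llf).all()
                    and np.isfinite(g_lb1).all()):
                return -np.inf, np.zeros_like(theta)

        g_b0_pc = g_b0.reshape(self._P, self._C)
        g_ll_pc = g_llf.reshape(self._P, self._C)
        G_d0 = g_b0_pc.sum(axis=0)
        G_dl = g_ll_pc.sum(axis=0)

        grad = np.empty_like(theta)
        grad[self._sl_a0] = g_b0_pc.sum(axis=1) - ra / hp.prey_beta0_scale ** 2
        grad[self._sl_al] = g_ll_pc.sum(axis=1) \
            - rl / hp.prey_log_lambda_scale ** 2
        grad[self._i_mu_d0] = G_d0.sum() \
            - (mu_d0 - hp.predator_beta0.mu_loc) / hp.predator_beta0.mu_scale ** 2
        grad[self._i_mu_dl] = G_dl.sum() \
            - (mu_dl - hp.predator_log_lambda.mu_loc) \
            / hp.predator_log_lambda.mu_scale ** 2
        grad[self._i_mu_b1] = g_lb1.sum() \
            - (mu_b1 - hp.log_beta1.mu_loc) / hp.log_beta1.mu_scale ** 2
        grad[self._sl_zd0] = sig[0] * G_d0 - z_d0
        grad[self._sl_zdl] = sig[1] * G_dl - z_dl
        grad[self._sl_zg0] = sig[2] * g_b0 - z_g0
        grad[self._sl_zgl] = sig[3] * g_llf - z_gl
        grad[self._sl_zb1] = sig[4] * g_lb1 - z_b1
        grad[self._sl_ls] = np.array([
            sig[0] * (z_d0 @ G_d0),
            sig[1] * (z_dl @ G_dl),
            sig[2] * (z_g0 @ g_b0),
            sig[3] * (z_gl @ g_llf),
            sig[4] * (z_b1 @ g_lb1),
        ]) + 1.0 - sr * sr * 1.0
        if not np.isfinite(grad).all():
            return -np.inf, np.zeros_like(theta)
        return lp, grad

    def _gibbs_interweave(self, theta: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
        """Interweaved Gibbs updates of the prior-only directions.

        Two kinds of exact conditional draws are composed with each
        NUTS step, both cheap because the likelihood is invariant:

        * **Recentering translations.**  The likelihood sees only the
          sums ``alpha + delta + gamma``, so shifting mass between a
          prey effect and the matching predator/interaction effects
          moves along a likelihood-null direction whose conditional
          density (priors only) is a univariate Gaussian.
        * **Location/scale updates.**  Conditional on the effects, the
          data carry no information about a family's location or scale:
          locations are conjugate Normal draws, scales are
          slice-sampled from a univariate density.

        The standard-Normal offsets are then recoded so the effects
        stay numerically unchanged.  Composed with NUTS this breaks the
        funnel and ridge directions that slow plain HMC.
        """
        hp = self.hyperpriors
        theta = theta.copy()
        (a0, al, mu_d0, mu_dl, mu_b1, sig,
         z_d0, z_dl, z_g0, z_gl, z_b1, d0, dl, b0, ll, lb1) = \
            self._unpack(theta)
        P, C = self._P, self._C
        a0 = a0.copy()
        al = al.copy()
        d0 = d0.copy()
        dl = dl.copy()
        g0 = (sig[2] * z_g0).reshape(P, C).copy()
        gl = (sig[3] * z_gl).reshape(P, C).copy()
        lb1 = lb1.copy()
        ls = theta[self._sl_ls].copy()

        def translate(alpha, delta, gamma, a_loc, a_sc, mu_del, s_del, s_gam):
            """Likelihood-null recentering moves for one channel."""
            # whole-vector shift between prey and predator effects
            prec = P / a_sc ** 2 + C / s_del ** 2
            mean = ((a_loc - alpha).sum() / a_sc ** 2
                    + (delta - mu_del).sum() / s_del ** 2) / prec
            t = mean + rng.standard_normal() / math.sqrt(prec)
            alpha += t
            delta -= t
            # per-prey shift between alpha[p] and interaction row p
            prec = 1.0 / a_sc ** 2 + C / s_gam ** 2
            mean = ((a_loc - alpha) / a_sc ** 2
                    + gamma.sum(axis=1) / s_gam ** 2) / prec
            t = mean + rng.standard_normal(P) / math.sqrt(prec)
            alpha += t
            gamma -= t[:, None]
            # per-predator shift between delta[c] and interaction col c
            prec = 1.0 / s_del ** 2 + P / s_gam ** 2
            mean = ((mu_del - delta) / s_del ** 2
                    + gamma.sum(axis=0) / s_gam ** 2) / prec
            t = mean + rng.standard_normal(C) / math.sqrt(prec)
            delta += t
            gamma -= t[None, :]

        translate(a0, d0, g0, hp.prey_beta0_loc, hp.prey_beta0_scale,
                  mu_d0, sig[0], sig[2])
        translate(al, dl, gl, hp.prey_log_lambda_loc, hp.prey_log_lambda_scale,
                  mu_dl, sig[1], sig[3])

        # family locations (conjugate Normal) and scales (slice) in the
        # centred ("sufficient") parameterization
        fams = (
            (self._sl_zd0, d0, self._i_mu_d0, hp.predator_beta0, 0),
            (self._sl_zdl, dl, self._i_mu_dl, hp.predator_log_lambda, 1),
            (self._sl_zg0, g0.ravel(), None, hp.interaction_beta0, 2),
            (self._sl_zgl, gl.ravel(), None, hp.interaction_log_lambda, 3),
            (self._sl_zb1, lb1, self._i_mu_b1, hp.log_beta1, 4),
        )
        for sl, eff, i_mu, fam, j in fams:
            n = eff.size
            sigma = float(np.exp(ls[j]))
            if i_mu is not None:
                prec = 1.0 / fam.mu_scale ** 2 + n / sigma ** 2
                mean = (fam.mu_loc / fam.mu_scale ** 2
                        + eff.sum() / sigma ** 2) / prec
                mu = mean + rng.standard_normal() / math.sqrt(prec)
                theta[i_mu] = mu
            else:
                mu = 0.0
            a_half = 0.5 * float(np.sum((eff - mu) ** 2))
            s2 = fam.sigma_scale ** 2

            def logf(l, _a=a_half, _n=n, _s2=s2):
                if abs(l) > 300.0:
                    return -np.inf
                return ((1.0 - _n) * l - math.exp(2.0 * l) / (2.0 * _s2)
                        - _a * math.exp(-2.0 * l))

            ls[j] = hmc.slice_sample_1d(logf, float(ls[j]), rng)
            sigma = float(np.exp(ls[j]))
            # recode offsets so effects stay numerically identical
            theta[sl] = (eff - mu) / sigma
        theta[self._sl_a0] = a0
        theta[self._sl_al] = al
        theta[self._sl_ls] = ls
        return theta

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        chains: int = 3,
        seed: int = 0,
        target_accept: float = 0.95,
        max_depth: int = 6,
        gibbs_scales: bool = True,
    ) -> "PredationResults":
        """Sample the joint posterior with HMC.

        Three chains by default; runs are bit-reproducible given
        identical settings and ``seed``.  Warns (:class:`SaturationWarning`)
        when every field test is positive, in which case the predation
        rates are prior-driven.
        """
        if self._field_k.sum() == self._field_n.sum():
            warnings.warn(
                "every field test is positive: detection is saturated and "
                "predation rates are not identified by the data",
                SaturationWarning, stacklevel=2)

        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(chains)
        all_draws = np.empty((chains, draws, self.n_params))
        stats = []
        for ci in range(chains):
            rng = np.random.default_rng(chain_seeds[ci])
            theta0 = rng.normal(0.0, 0.1, self.n_params)
            theta0[self._sl_ls] = np.log(0.5) + rng.normal(0.0, 0.1, 5)
            ch, st = hmc.sample(
                self.logpost_and_grad, theta0, warmup, draws, rng,
                target_accept=target_accept, max_depth=max_depth,
                interleave=self._gibbs_interweave if gibbs_scales else None)
            all_draws[ci] = ch
            stats.append(st)
            logger.info("chain %d: step=%.3g accept=%.2f divergences=%d",
                        ci, st.step_size, st.mean_accept, st.divergences)

        posterior = self._constrain(all_draws)
        settings = dict(draws=draws, warmup=warmup, chains=chains, seed=seed,
                        target_accept=target_accept, max_depth=max_depth,
                        gibbs_scales=gibbs_scales)
        return PredationResults(self.registry, posterior, settings, stats,
                                model=self)

    def _constrain(self, theta: np.ndarray) -> Dict[str, np.ndarray]:
        """Map (chains, draws, dim) unconstrained draws to named arrays."""
        P, C = self._P, self._C
        sh = theta.shape[:2]
        a0 = theta[..., self._sl_a0]
        al = theta[..., self._sl_al]
        mu_d0 = theta[..., self._i_mu_d0]
        mu_dl = theta[..., self._i_mu_dl]
        mu_b1 = theta[..., self._i_mu_b1]
        sig = np.exp(theta[..., self._sl_ls])
        d0 = mu_d0[..., None] + sig[..., 0:1] * theta[..., self._sl_zd0]
        dl = mu_dl[..., None] + sig[..., 1:2] * theta[..., self._sl_zdl]
        g0 = (sig[..., 2:3] * theta[..., self._sl_zg0]).reshape(*sh, P, C)
        gl = (sig[..., 3:4] * theta[..., self._sl_zgl]).reshape(*sh, P, C)
        lb1 = (mu_b1[..., None] + sig[..., 4:5] * theta[..., self._sl_zb1]
               ).reshape(*sh, P, C)
        b0 = a0[..., :, None] + d0[..., None, :] + g0
        ll = al[..., :, None] + dl[..., None, :] + gl
        beta1 = np.exp(lb1)
        lam = np.exp(ll)
        integral = np.logaddexp(0.0, b0) / beta1
        return {
            "alpha_beta0": a0, "alpha_log_lambda": al,
            "delta_beta0": d0, "delta_log_lambda": dl,
            "gamma_beta0": g0, "gamma_log_lambda": gl,
            "log_beta1": lb1,
            "mu_predator_beta0": mu_d0, "mu_predator_log_lambda": mu_dl,
            "mu_log_beta1": mu_b1,
            "sigma_predator_beta0": sig[..., 0],
            "sigma_predator_log_lambda": sig[..., 1],
            "sigma_interaction_beta0": sig[..., 2],
            "sigma_interaction_log_lambda": sig[..., 3],
            "sigma_log_beta1": sig[..., 4],
            "beta0": b0, "beta1": beta1, "lam": lam,
            "daily_rate": HOURS_PER_DAY * lam,
            "detectability": integral,
            "p_detect": -np.expm1(-lam * integral),
        }


def fit_model(lab, field, hyperpriors=None, **settings) -> "PredationResults":
    """Convenience wrapper: build a :class:`PredationModel` and fit it."""
    return PredationModel(lab, field, hyperpriors=hyperpriors).fit(**settings)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

#: Parameters whose convergence is gated (every sampled quantity, on its
#: interpretable scale).
GATED_PARAMS = (
    "alpha_beta0", "alpha_log_lambda", "delta_beta0", "delta_log_lambda",
    "gamma_beta0", "gamma_log_lambda", "log_beta1",
    "mu_predator_beta0", "mu_predator_log_lambda", "mu_log_beta1",
    "sigma_predator_beta0", "sigma_predator_log_lambda",
    "sigma_interaction_beta0", "sigma_interaction_log_lambda",
    "sigma_log_beta1",
)


@dataclass
class FitReport:
    """Posterior summaries: daily rates, digestion curves, diagnostics."""

    daily_rates: pd.DataFrame
    digestion: pd.DataFrame
    psrf: pd.DataFrame

    def __str__(self) -> str:
        out = ["Daily predation rates (events/day)",
               self.daily_rates.to_string(float_format=lambda v: f"{v:.4g}"),
               "",
               f"max classic PSRF = {self.psrf['psrf'].max():.4f}, "
               f"max rank-normalized split R-hat = {self.psrf['rhat_rank'].max():.4f}"]
        return "\n".join(out)


class PredationResults:
    """Posterior draws and everything derived from them.

    Draw arrays are indexed ``(chain, draw, ...)``; rates are stored per
    hour (``lam``) and per day (``daily_rate``).  All quantile summaries
    use lower interpolation so that reported values are actual draws.
    """

    def __init__(self, registry: Registry, posterior: Dict[str, np.ndarray],
                 settings: dict, sampler_stats=None, model: Optional[PredationModel] = None):
        self.registry = registry
        self.posterior = posterior
        self.settings = settings
        self.sampler_stats = sampler_stats or []
        self.model = model

    @property
    def n_chains(self) -> int:
        return self.posterior["daily_rate"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.posterior["daily_rate"].shape[1]

    def __repr__(self) -> str:
        r = self.registry
        return (f"<PredationResults: {r.n_predators} predators x {r.n_prey} prey, "
                f"{self.n_chains} chains x {self.n_draws} draws>")

    # -- convergence ----------------------------------------------------

    def gelman_rubin(self, param: str) -> np.ndarray:
        """Classic PSRF for every element of one parameter array."""
        arr = self.posterior[param]
        flat = arr.reshape(self.n_chains, self.n_draws, -1)
        out = np.array([gelman_rubin(flat[:, :, j])
                        for j in range(flat.shape[2])])
        return out.reshape(arr.shape[2:]) if arr.ndim > 2 else float(out[0])

    def rhat(self, param: str) -> np.ndarray:
        """Rank-normalized split R-hat (modern default, via arviz)."""
        import arviz as az

        arr = self.posterior[param]
        return np.asarray(az.rhat(az.convert_to_dataset(arr))["x"])

    def psrf_table(self, params: Sequence[str] = GATED_PARAMS) -> pd.DataFrame:
        """Both convergence diagnostics for every gated parameter element."""
        rows = []
        for name in params:
            classic = np.atleast_1d(self.gelman_rubin(name))
            rank = np.atleast_1d(self.rhat(name))
            for j, (c, r) in enumerate(zip(classic.ravel(), rank.ravel())):
                label = name if classic.size == 1 else f"{name}[{j}]"
                rows.append((label, c, r))
        return pd.DataFrame(rows, columns=["parameter", "psrf", "rhat_rank"])

    # -- summaries ------------------------------------------------------

    def _pair_frame(self, arr: np.ndarray,
                    quantiles: Sequence[float]) -> pd.DataFrame:
        """Summaries of a (chain, draw, prey, predator) array per pair."""
        flat = arr.reshape(-1, self.registry.n_prey, self.registry.n_predators)
        idx = pd.MultiIndex.from_product(
            [self.registry.predators, self.registry.prey],
            names=["predator_code", "prey"])
        rows = {}
        rows["mean"] = flat.mean(axis=0).T.ravel()
        rows["sd"] = flat.std(axis=0, ddof=1).T.ravel()
        for q in quantiles:
            rows[f"q{q:g}"] = np.quantile(
                flat, q, axis=0, method=QUANTILE_METHOD).T.ravel()
        df = pd.DataFrame(rows, index=idx)
        df.insert(0, "median", np.quantile(
            flat, 0.5, axis=0, method=QUANTILE_METHOD).T.ravel())
        return df

    def daily_rate_summary(
        self, quantiles: Sequence[float] = (0.05, 0.25, 0.75, 0.95),
    ) -> pd.DataFrame:
        """Per-pair summaries of the daily predation rate (events/day)."""
        return self._pair_frame(self.posterior["daily_rate"], quantiles)

    def digestion_summary(
        self, quantiles: Sequence[float] = (0.05, 0.95),
    ) -> pd.DataFrame:
        """Per-pair summaries of beta0, beta1 and the detectability window."""
        parts = []
        for name in ("beta0", "beta1", "detectability"):
            df = self._pair_frame(self.posterior[name], quantiles)
            df.columns = [f"{name}_{c}" for c in df.columns]
            parts.append(df)
        return pd.concat(parts, axis=1)

    def summary(self, quantiles: Sequence[float] = (0.05, 0.25, 0.75, 0.95)
                ) -> FitReport:
        """Full report: rates, digestion parameters and diagnostics."""
        return FitReport(
            daily_rates=self.daily_rate_summary(quantiles),
            digestion=self.digestion_summary(),
            psrf=self.psrf_table(),
        )

    # -- posterior-predictive goodness of fit ---------------------------

    def posterior_predictive_check(
        self, field: Optional[pd.DataFrame] = None,
    ) -> pd.DataFrame:
        """Observed positive frequencies against posterior p(I) intervals.

        For each (predator, prey) present in the field data: posterior
        quantiles of the detection probability and the observed
        frequency.  ``attrs`` carries the fractions of cells whose
        frequency lies inside the central 95% and 50% intervals.
        Registry species absent from the field data are excluded with a
        logged notice.
        """
        if field is None:
            if self.model is None:
                raise ValueError("no field data attached; pass `field`")
            field = self.model.field
        field = validate_field(field)
        p = self.posterior["p_detect"].reshape(
            -1, self.registry.n_prey, self.registry.n_predators)

        seen = set(map(tuple, field[["predator_code", "prey"]].drop_duplicates()
                       .itertuples(index=False)))
        missing = [c for c in self.registry.predators
                   if not any(c == s[0] for s in seen)]
        if missing:
            logger.info("species without field observations excluded from the "
                        "predictive check: %s", ", ".join(missing))

        rows = []
        grouped = field.groupby(["predator_code", "prey"])["detected"]
        for (pred, prey), g in grouped:
            ip = self.registry.prey_index(prey)
            ic = self.registry.predator_index(pred)
            draws = p[:, ip, ic]
            q = np.quantile(draws, [0.025, 0.25, 0.75, 0.975],
                            method=QUANTILE_METHOD)
            freq = g.mean()
            rows.append({
                "predator_code": pred, "prey": prey, "n": int(g.count()),
                "observed_freq": freq,
                "q2.5": q[0], "q25": q[1], "q75": q[2], "q97.5": q[3],
                "inside_95": bool(q[0] <= freq <= q[3]),
                "inside_50": bool(q[1] <= freq <= q[2]),
            })
        out = pd.DataFrame(rows)
        out.attrs["fraction_inside_95"] = float(out["inside_95"].mean())
        out.attrs["fraction_inside_50"] = float(out["inside_50"].mean())
        return out

    # -- biocontrol indicator -------------------------------------------

    def biocontrol_indicator(self, abundance, prey, n_draws: int = 100,
                             seed: Optional[int] = None):
        """Community-scale indicator; see :func:`molpred.biocontrol.indicator`."""
        from .biocontrol import indicator

        return indicator(self, abundance, prey, n_draws=n_draws, seed=seed)

    # -- plotting --------------------------------------------------------

    def plot_digestion_curves(self, **kwargs):
        from .plotting import plot_digestion_curves

        return plot_digestion_curves(self, **kwargs)

    def plot_daily_rates(self, **kwargs):
        from .plotting import plot_daily_rates

        return plot_daily_rates(self, **kwargs)

    def plot_ppc(self, **kwargs):
        from .plotting import plot_ppc

        return plot_ppc(self, **kwargs)

    # -- interop and persistence -----------------------------------------

    def to_inference_data(self):
        """Posterior as an arviz ``InferenceData`` (coords attached)."""
        import arviz as az

        coords = {"prey": list(self.registry.prey),
                  "predator": list(self.registry.predators)}
        dims = {}
        for name, arr in self.posterior.items():
            if arr.ndim == 4:
                dims[name] = ["prey", "predator"]
            elif arr.ndim == 3:
                dims[name] = (["prey"] if arr.shape[2] == self.registry.n_prey
                              and name.startswith("alpha") else ["predator"])
        return az.from_dict(posterior=self.posterior, coords=coords, dims=dims)

    def save(self, path) -> None:
        """Persist draws (`.npz`) plus a JSON sidecar with metadata."""
        path = str(path)
        np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                            **self.posterior)
        meta = {
            "prey": list(self.registry.prey),
            "predators": list(self.registry.predators),
            "settings": self.settings,
        }
        side = (path[:-4] if path.endswith(".npz") else path) + ".json"
        with open(side, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "PredationResults":
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with np.load(path) as z:
            posterior = {k: z[k] for k in z.files}
        with open(path[:-4] + ".json") as fh:
            meta = json.load(fh)
        reg = Registry(prey=tuple(meta["prey"]), predators=tuple(meta["predators"]))
        return cls(reg, posterior, meta.get("settings", {}))
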