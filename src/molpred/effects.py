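"""Additive effect decomposition and hierarchical prior structure.

Every predator--prey pair (p = prey, c = predator) gets its own
digestion curve and predation rate, decomposed additively:

    beta0(p, c)   = alpha_b0(p) + delta_b0(c) + gamma_b0(p, c)
    ln lam(p, c)  = alpha_l(p)  + delta_l(c)  + gamma_l(p, c)

with a single log-normal family for the decay slopes,
``ln beta1(p, c) ~ Normal(mu, sigma)`` shared across all pairs.

Predator effects, interaction effects and log-slopes are hierarchized:
drawn from Normal distributions whose location/scale hyperparameters sit
at the level of the whole taxonomic group, so information flows from
well-observed species to rare ones.  Prey effects are few and
taxonomically heterogeneous, so they carry fixed (non-hierarchized)
Normal priors.  Interaction-family locations are pinned at 0 to keep
the additive decomposition softly identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import halfnorm, norm

__all__ = [
    "Registry",
    "EffectDecomposition",
    "FamilyPrior",
    "HyperPriors",
    "Hyperparameters",
    "assemble_beta0",
    "assemble_log_lambda",
    "prior_logdensity",
]


@dataclass(frozen=True)
class Registry:
    """Declared prey and predator label sets, in fixed order."""

    prey: tuple
    predators: tuple

    def __post_init__(self):
        for name, labels in (("prey", self.prey), ("predators", self.predators)):
            if len(labels) == 0:
                raise ValueError(f"{name} registry is empty")
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels in {name} registry")
            if any(not str(l) for l in labels):
                raise ValueError(f"empty label in {name} registry")

    @property
    def n_prey(self) -> int:
        return len(self.prey)

    @property
    def n_predators(self) -> int:
        return len(self.predators)

    @property
    def n_pairs(self) -> int:
        return self.n_prey * self.n_predators

    def prey_index(self, label: str) -> int:
        try:
            return self.prey.index(label)
        except ValueError:
            raise KeyError(f"unknown prey {label!r}") from None

    def predator_index(self, label: str) -> int:
        try:
            return self.predators.index(label)
        except ValueError:
            raise KeyError(f"unknown predator {label!r}") from None

    @classmethod
    def from_data(
        cls,
        lab: Optional[pd.DataFrame] = None,
        field_df: Optional[pd.DataFrame] = None,
    ) -> "Registry":
        """Union of labels seen in either dataset (sorted for stability).

        Species present in only one dataset are retained: the hierarchy
        supplies the information the other dataset lacks.
        """
        prey: set = set()
        preds: set = set()
        for df in (lab, field_df):
            if df is not None and len(df):
                prey.update(map(str, df["prey"].unique()))
                preds.update(map(str, df["predator_code"].unique()))
        return cls(prey=tuple(sorted(prey)), predators=tuple(sorted(preds)))


@dataclass
class EffectDecomposition:
    """One realisation of all additive effects (arrays over the registry).

    Shapes: prey effects ``(n_prey,)``, predator effects
    ``(n_predators,)``, interaction effects and log-slopes
    ``(n_prey, n_predators)``.
    """

    registry: Registry
    alpha_beta0: np.ndarray
    delta_beta0: np.ndarray
    gamma_beta0: np.ndarray
    alpha_lam: np.ndarray
    delta_lam: np.ndarray
    gamma_lam: np.ndarray
    log_beta1: np.ndarray

    def __post_init__(self):
        P, C = self.registry.n_prey, self.registry.n_predators
        shapes = {
            "alpha_beta0": (P,),
            "delta_beta0": (C,),
            "gamma_beta0": (P, C),
            "alpha_lam": (P,),
            "delta_lam": (C,),
            "gamma_lam": (P, C),
            "log_beta1": (P, C),
        }
        for name, shp in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shp:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shp}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    # -- assembled parameter grids ------------------------------------
    def beta0(self) -> np.ndarray:
        return self.alpha_beta0[:, None] + self.delta_beta0[None, :] + self.gamma_beta0

    def log_lambda(self) -> np.ndarray:
        return self.alpha_lam[:, None] + self.delta_lam[None, :] + self.gamma_lam

    def beta1(self) -> np.ndarray:
        return np.exp(self.log_beta1)

    def lam(self) -> np.ndarray:
        return np.exp(self.log_lambda())


def assemble_beta0(effects: EffectDecomposition, prey: str, predator: str) -> float:
    """``beta0(p, c) = alpha_b0(p) + delta_b0(c) + gamma_b0(p, c)``."""
    ip = effects.registry.prey_index(prey)
    ic = effects.registry.predator_index(predator)
    return float(
        effects.alpha_beta0[ip] + effects.delta_beta0[ic] + effects.gamma_beta0[ip, ic]
    )


def assemble_log_lambda(effects: EffectDecomposition, prey: str, predator: str) -> float:
    """``ln lam(p, c) = alpha_l(p) + delta_l(c) + gamma_l(p, c)``.

    Exponentiating the assembled value keeps every predation rate
    strictly positive.
    """
    ip = effects.registry.prey_index(prey)
    ic = effects.registry.predator_index(predator)
    return float(
        effects.alpha_lam[ip] + effects.delta_lam[ic] + effects.gamma_lam[ip, ic]
    )


@dataclass(frozen=True)
class FamilyPrior:
    """Hyperprior constants for one hierarchized effect family.

    The family's effects are ``Normal(mu, sigma)`` with
    ``mu ~ Normal(mu_loc, mu_scale)`` (unless the location is
    structurally pinned at 0) and ``sigma ~ HalfNormal(sigma_scale)``.
    """

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 1.0
    mu_fixed: bool = False

    def __post_init__(self):
        if self.mu_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("hyperprior scales must be strictly positive")


@dataclass(frozen=True)
class HyperPriors:
    """All fixed prior constants of the model (config-overridable).

    Defaults are weakly informative on the logit / log scales: prey
    effects Normal(0, 2) fixed; hierarchized families with
    Normal(0, 1) location hyperpriors and HalfNormal(1) scale
    hyperpriors; interaction locations pinned at 0.
    """

    prey_beta0_loc: float = 0.0
    prey_beta0_scale: float = 2.0
    prey_log_lambda_loc: float = 0.0
    prey_log_lambda_scale: float = 2.0
    predator_beta0: FamilyPrior = field(default_factory=FamilyPrior)
    predator_log_lambda: FamilyPrior = field(default_factory=FamilyPrior)
    interaction_beta0: FamilyPrior = field(default_factory=lambda: FamilyPrior(mu_fixed=True))
    interaction_log_lambda: FamilyPrior = field(default_factory=lambda: FamilyPrior(mu_fixed=True))
    log_beta1: FamilyPrior = field(default_factory=FamilyPrior)

    def __post_init__(self):
        if self.prey_beta0_scale <= 0 or self.prey_log_lambda_scale <= 0:
            raise ValueError("prey prior scales must be strictly positive")
        # interaction locations are pinned regardless of configuration
        object.__setattr__(self, "interaction_beta0",
                           replace(self.interaction_beta0, mu_fixed=True))
        object.__setattr__(self, "interaction_log_lambda",
                           replace(self.interaction_log_lambda, mu_fixed=True))

    # -- configuration round trip -------------------------------------
    _FAMILIES = ("predator_beta0", "predator_log_lambda",
                 "interaction_beta0", "interaction_log_lambda", "log_beta1")

    def to_dict(self) -> dict:
        d = {
            "prey_beta0": {"loc": self.prey_beta0_loc, "scale": self.prey_beta0_scale},
            "prey_log_lambda": {
                "loc": self.prey_log_lambda_loc,
                "scale": self.prey_log_lambda_scale,
            },
        }
        for name in self._FAMILIES:
            fam: FamilyPrior = getattr(self, name)
            entry = {"sigma_scale": fam.sigma_scale}
            if not fam.mu_fixed:
                entry.update({"mu_loc": fam.mu_loc, "mu_scale": fam.mu_scale})
            d[name] = entry
        return d

    @classmethod
    def from_dict(cls, d: Optional[dict]) -> "HyperPriors":
        if not d:
            return cls()
        kw = {}
        if "prey_beta0" in d:
            kw["prey_beta0_loc"] = float(d["prey_beta0"].get("loc", 0.0))
            kw["prey_beta0_scale"] = float(d["prey_beta0"].get("scale", 2.0))
        if "prey_log_lambda" in d:
            kw["prey_log_lambda_loc"] = float(d["prey_log_lambda"].get("loc", 0.0))
            kw["prey_log_lambda_scale"] = float(d["prey_log_lambda"].get("scale", 2.0))
        for name in cls._FAMILIES:
            if name in d:
                e = d[name]
                fixed = name.startswith("interaction")
                kw[name] = FamilyPrior(
                    mu_loc=float(e.get("mu_loc", 0.0)),
                    mu_scale=float(e.get("mu_scale", 1.0)),
                    sigma_scale=float(e.get("sigma_scale", 1.0)),
                    mu_fixed=fixed,
                )
        return cls(**kw)


@dataclass(frozen=True)
class Hyperparameters:
    """Sampled group-level locations and scales of the hierarchy."""

    mu_predator_beta0: float = 0.0
    sigma_predator_beta0: float = 1.0
    mu_predator_log_lambda: float = 0.0
    sigma_predator_log_lambda: float = 1.0
    sigma_interaction_beta0: float = 1.0
    sigma_interaction_log_lambda: float = 1.0
    mu_log_beta1: float = 0.0
    sigma_log_beta1: float = 1.0

    def __post_init__(self):
        for name in ("sigma_predator_beta0", "sigma_predator_log_lambda",
                     "sigma_interaction_beta0", "sigma_interaction_log_lambda",
                     "sigma_log_beta1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def prior_logdensity(
    effects: EffectDecomposition,
    hyper: Hyperparameters,
    hyperpriors: Optional[HyperPriors] = None,
) -> float:
    """Joint log-density of effects and hyperparameters under the prior.

    Sum of: Normal terms for hierarchized predator, interaction and
    log-slope effects given their group-level location/scale; fixed
    Normal terms for the (non-hierarchized) prey effects; Normal
    hyperprior terms for the free locations and HalfNormal terms for
    the scales.
    """
    hp = hyperpriors or HyperPriors()
    lp = 0.0
    # prey effects: fixed priors
    lp += float(np.sum(norm.logpdf(effects.alpha_beta0,
                                   hp.prey_beta0_loc, hp.prey_beta0_scale)))
    lp += float(np.sum(norm.logpdf(effects.alpha_lam,
                                   hp.prey_log_lambda_loc, hp.prey_log_lambda_scale)))
    # hierarchized families
    lp += float(np.sum(norm.logpdf(effects.delta_beta0,
                                   hyper.mu_predator_beta0, hyper.sigma_predator_beta0)))
    lp += float(np.sum(norm.logpdf(effects.delta_lam,
                                   hyper.mu_predator_log_lambda,
                                   hyper.sigma_predator_log_lambda)))
    lp += float(np.sum(norm.logpdf(effects.gamma_beta0,
                                   0.0, hyper.sigma_interaction_beta0)))
    lp += float(np.sum(norm.logpdf(effects.gamma_lam,
                                   0.0, hyper.sigma_interaction_log_lambda)))
    lp += float(np.sum(norm.logpdf(effects.log_beta1,
                                   hyper.mu_log_beta1, hyper.sigma_log_beta1)))
    # hyperpriors
    lp += float(norm.logpdf(hyper.mu_predator_beta0,
                            hp.predator_beta0.mu_loc, hp.predator_beta0.mu_scale))
    lp += float(norm.logpdf(hyper.mu_predator_log_lambda,
                            hp.predator_log_lambda.mu_loc,
                            hp.predator_log_lambda.mu_scale))
    lp += float(norm.logpdf(hyper.mu_log_beta1,
                            hp.log_beta1.mu_loc, hp.log_beta1.mu_scale))
    lp += float(halfnorm.logpdf(hyper.sigma_predator_beta0,
                                scale=hp.predator_beta0.sigma_scale))
    lp += float(halfnorm.logpdf(hyper.sigma_predator_log_lambda,
                                scale=hp.predator_log_lambda.sigma_scale))
    lp += float(halfnorm.logpdf(hyper.sigma_interaction_beta0,
                                scale=hp.interaction_beta0.sigma_scale))
    lp += float(halfnorm.logpdf(hyper.sigma_interaction_log_lambda,
                                scale=hp.interaction_log_lambda.sigma_scale))
    lp += float(halfnorm.logpdf(hyper.sigma_log_beta1,
                                scale=hp.log_beta1.sigma_scale))
    return lp
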