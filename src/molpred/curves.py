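"""Deterministic kernel of the predation--digestion model.

Molecular gut-content tests are binary: a predator either tests positive
for a prey's DNA or it does not.  Two processes generate those outcomes:

* **Digestion** degrades prey DNA, so the probability ``pi(t)`` of a
  positive test ``t`` hours after a meal decays as a logistic curve,
  ``logit pi(t) = beta0 - beta1 * t`` with decay slope ``beta1 > 0``.
* **Predation** follows a homogeneous Poisson process with intensity
  ``lam`` meals per hour.  Thinning each past meal by its current
  detectability makes the number of *detectable* meals at capture time
  Poisson with mean ``lam * I``, where ``I = integral_0^inf pi(t) dt``
  is the detectability window in hours.  A field test is positive as
  soon as one past meal is detectable, so
  ``P(positive) = 1 - exp(-lam * I)``.

This module holds the closed forms and the two Bernoulli log-likelihoods
(laboratory feeding trial; field captures).  Everything is pure and
vectorised; the hierarchical prior and the sampler live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DigestionParams",
    "PredationRate",
    "HOURS_PER_DAY",
    "detection_probability",
    "detectability_integral",
    "field_positive_probability",
    "lab_loglik",
    "field_loglik",
]

#: Reporting convention: rates are modelled per hour, reported per day.
HOURS_PER_DAY = 24.0

Pair = Tuple[str, str]  # (predator_code, prey)


@dataclass(frozen=True)
class DigestionParams:
    """Logistic DNA-decay curve of one predator--prey pair.

    Parameters
    ----------
    beta0 : float
        Log-odds of detection immediately after the meal (unitless).
    beta1 : float
        Decay slope per hour; strictly positive.
    """

    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")
        if not (np.isfinite(self.beta1) and self.beta1 > 0):
            raise ValueError(f"beta1 must be strictly positive, got {self.beta1}")

    def pi(self, t):
        """Detection probability ``t`` hours after feeding."""
        return detection_probability(self.beta0, self.beta1, t)

    def integral(self) -> float:
        """Detectability window ``I`` in hours."""
        return detectability_integral(self.beta0, self.beta1)

    def half_life(self) -> float:
        """Time at which detection probability crosses 1/2 (hours).

        Negative when detection starts below 1/2 (``beta0 < 0``).
        """
        return self.beta0 / self.beta1


@dataclass(frozen=True)
class PredationRate:
    """Mean number of predation events per hour for one pair."""

    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and self.lam >= 0):
            raise ValueError(f"lam must be nonnegative and finite, got {self.lam}")

    @property
    def daily(self) -> float:
        """Rate on the reporting scale, events per day."""
        return HOURS_PER_DAY * self.lam


def _validate_beta1(beta1) -> np.ndarray:
    beta1 = np.asarray(beta1, dtype=float)
    if np.any(~np.isfinite(beta1)) or np.any(beta1 <= 0):
        raise ValueError("beta1 must be finite and strictly positive")
    return beta1


def detection_probability(beta0, beta1, t):
    """Probability of detecting prey DNA ``t`` hours after a meal.

    ``expit(beta0 - beta1 * t)``: strictly decreasing in ``t`` and
    ``beta1``, increasing in ``beta0``.  Stable for exponents up to
    +-700.  Accepts scalars or broadcastable arrays.
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = _validate_beta1(beta1)
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time since feeding must be finite and >= 0")
    out = expit(beta0 - beta1 * t)
    return float(out) if out.ndim == 0 else out


def detectability_integral(beta0, beta1):
    """Area under the digestion curve, ``I = ln(1 + e^{beta0}) / beta1``.

    The expected detectability window in hours; ``lam * I`` is the
    expected number of still-detectable past meals at capture time.
    Uses ``logaddexp`` so large ``|beta0|`` cannot overflow.
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = _validate_beta1(beta1)
    out = np.logaddexp(0.0, beta0) / beta1
    return float(out) if out.ndim == 0 else out


def field_positive_probability(lam, integral):
    """Probability that a field-caught predator tests positive.

    ``p = 1 - exp(-lam * I)``: at least one of the Poisson(lam * I)
    detectable meals is present.  Monotone increasing in both
    arguments; 0 when either is 0.
    """
    lam = np.asarray(lam, dtype=float)
    integral = np.asarray(integral, dtype=float)
    if np.any(~np.isfinite(lam)) or np.any(lam < 0):
        raise ValueError("lam must be nonnegative and finite")
    if np.any(~np.isfinite(integral)) or np.any(integral < 0):
        raise ValueError("integral must be nonnegative and finite")
    out = -np.expm1(-lam * integral)
    return float(out) if out.ndim == 0 else out


def _bernoulli_logpmf(detected, p):
    # log P(d | p) with 0*log(0) handled: p in [0, 1]
    detected = np.asarray(detected, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(detected > 0, np.log(p), np.log1p(-p))
    # 0 * -inf situations cannot arise: detected selects exactly one branch
    return lp


def lab_loglik(
    data: pd.DataFrame,
    params_by_pair: Mapping[Pair, DigestionParams],
) -> float:
    """Feeding-trial log-likelihood.

    Each row of ``data`` (columns ``predator_code``, ``prey``,
    ``hours_since_feeding``, ``detected``) is a Bernoulli trial with
    success probability ``pi(hours_since_feeding)`` of its pair's
    digestion curve.

    Raises
    ------
    KeyError
        If a row references a (predator_code, prey) pair absent from
        ``params_by_pair``.
    """
    total = 0.0
    for (pred, prey), grp in data.groupby(["predator_code", "prey"], sort=False):
        if (pred, prey) not in params_by_pair:
            raise KeyError(f"no digestion parameters for pair {(pred, prey)!r}")
        params = params_by_pair[(pred, prey)]
        p = params.pi(grp["hours_since_feeding"].to_numpy(dtype=float))
        total += float(np.sum(_bernoulli_logpmf(grp["detected"].to_numpy(), p)))
    return total


def field_loglik(
    data: pd.DataFrame,
    lam_by_pair: Mapping[Pair, PredationRate],
    integral_by_pair: Mapping[Pair, float],
) -> float:
    """Field-capture log-likelihood.

    Each (individual, prey) row is an independent Bernoulli trial with
    success probability ``1 - exp(-lam * I)`` of its pair.  Outcomes of
    the same individual for different prey are treated as independent
    (one rate per pair; no cross-prey dependence is modelled).

    Raises
    ------
    KeyError
        If a row references a pair missing from either mapping.
    """
    total = 0.0
    for (pred, prey), grp in data.groupby(["predator_code", "prey"], sort=False):
        key = (pred, prey)
        if key not in lam_by_pair or key not in integral_by_pair:
            raise KeyError(f"no field parameters for pair {key!r}")
        p = field_positive_probability(lam_by_pair[key].lam, integral_by_pair[key])
        total += float(np.sum(_bernoulli_logpmf(grp["detected"].to_numpy(), p)))
    return total
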