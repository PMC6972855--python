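"""Empirical-Bayes inverse-gamma prior on the per-feature variance.

The variance of the log-abundance model is assumed to share a common
prior across features,

    sigma_k^2 ~ Inv-Gamma(d0/2, d0*s0^2/2),

whose hyperparameters (d0, s0) are estimated from the data in three
steps: (1) a rough per-feature sigma estimate from the truncated-normal
likelihood of the non-PMV observations; (2) a restriction to features
with enough non-PMVs to make that estimate meaningful; (3) a
method-of-moments fit of the inverse-gamma to the squared rough
estimates.  The two moment identities

    d0 s0^2 / (d0 - 2) = m      (prior mean of sigma^2)
    m^2 / (d0/2 - 2)   = v      (prior variance of sigma^2)

hold exactly, with m and v the sample mean and variance of sigma_hat^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, log_ndtr

from .data import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PriorHyperparams",
    "RoughSigmaResult",
    "rough_sigma",
    "select_prior_features",
    "estimate_hyperparameters",
    "log_prior",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: search window for the rough sigma estimate, on the sigma scale
SIGMA_SEARCH_BOUNDS = (1e-3, 1e3)


@dataclass
class PriorHyperparams:
    """Fitted inverse-gamma hyperparameters (d0 = degrees of freedom, s0 = scale)."""

    d0: float
    s0: float
    n_features_used: int = 0

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.s0 <= 0:
            raise ValueError(f"d0 and s0 must be positive, got {(self.d0, self.s0)}")

    @property
    def prior_mode(self) -> float:
        """Mode of the prior on sigma^2: d0*s0^2/(d0+2)."""
        return self.d0 * self.s0**2 / (self.d0 + 2.0)

    @property
    def prior_mean(self) -> float:
        """Mean of the prior on sigma^2 (finite for d0 > 2)."""
        return self.d0 * self.s0**2 / (self.d0 - 2.0)


@dataclass
class RoughSigmaResult:
    sigma_hat: float
    converged: bool
    n_nonpmv_used: int


def rough_sigma(feature_values, lam: float) -> RoughSigmaResult:
    """Rough sigma estimate from the truncated-normal likelihood of non-PMVs.

    Non-PMV log abundances follow a normal truncated at the detection
    limit ``lam``; with the mean pinned at their sample mean, sigma is the
    maximizer of

        prod_i phi((l_i - mu)/sigma) / sigma / [1 - Phi((lam - mu)/sigma)]

    found by bounded search on log sigma.  This estimate only feeds the
    hyperparameter fit; model inference uses the posterior-mode sigma.
    """
    v = np.asarray(feature_values, dtype=float)
    logs = np.log(v[v > 0])
    n = logs.size
    if n < 2:
        raise ValueError(f"rough sigma needs at least 2 non-PMVs, got {n}")
    mu = logs.mean()
    resid_sq = float(np.sum((logs - mu) ** 2))
    z0 = lam - mu

    def negloglik(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        # sum log phi - n log sigma - n log(1 - Phi((lam-mu)/sigma))
        return -(
            -0.5 * resid_sq / sigma**2
            - n * _LOG_SQRT_2PI
            - n * log_sigma
            - n * log_ndtr(-z0 / sigma)
        )

    lo, hi = np.log(SIGMA_SEARCH_BOUNDS[0]), np.log(SIGMA_SEARCH_BOUNDS[1])
    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    if res.success:
        return RoughSigmaResult(float(np.exp(res.x)), True, n)
    # fall back to the uncensored maximum-likelihood sd (divide by n)
    logger.warning("rough sigma search failed; falling back to uncensored MLE sd")
    sd = float(np.sqrt(resid_sq / n))
    return RoughSigmaResult(max(sd, SIGMA_SEARCH_BOUNDS[0]), False, n)


def select_prior_features(
    matrix: AbundanceMatrix, min_nonpmv: int = 10, fallback_top: int = 30
) -> list[str]:
    """Features eligible for hyperparameter estimation.

    Features with at least ``min_nonpmv`` non-PMV observations (both
    groups combined); when fewer than ``fallback_top`` such features
    exist, the ``fallback_top`` features with the smallest PMV proportion
    are used instead (ties broken by feature order).
    """
    n_nonpmv = (matrix.values > 0).sum(axis=1)
    eligible = [f for f, n in zip(matrix.feature_ids, n_nonpmv) if n >= min_nonpmv]
    if len(eligible) >= fallback_top:
        return eligible
    pmv_frac = (matrix.values == 0).mean(axis=1)
    order = np.argsort(pmv_frac, kind="stable")
    if matrix.n_features < fallback_top:
        logger.warning(
            "only %d features available for the prior fit (wanted %d)",
            matrix.n_features, fallback_top,
        )
        return [matrix.feature_ids[i] for i in order]
    return [matrix.feature_ids[i] for i in order[:fallback_top]]


def estimate_hyperparameters(sigma_hats) -> PriorHyperparams:
    """Method-of-moments inverse-gamma fit to the squared rough estimates.

    With m and v the sample mean and variance of sigma_hat^2,

        d0 = 2 m^2 / v + 4,   s0 = sqrt(m (d0 - 2) / d0).
    """
    s2 = np.asarray(sigma_hats, dtype=float) ** 2
    if s2.size < 2:
        raise ValueError("need at least 2 rough estimates to fit the prior")
    m = float(s2.mean())
    v = float(s2.var(ddof=1))
    if v <= 0:
        raise ValueError("degenerate variance spread: all rough estimates equal")
    d0 = 2.0 * m**2 / v + 4.0
    s0 = float(np.sqrt(m * (d0 - 2.0) / d0))
    return PriorHyperparams(d0=d0, s0=s0, n_features_used=int(s2.size))


def log_prior(sigma_sq: float, hp: PriorHyperparams) -> float:
    """Log inverse-gamma prior density of sigma^2.

    log of (d0 s0^2/2)^(d0/2) sigma^(-2(1+d0/2)) exp(-d0 s0^2/(2 sigma^2))
    / Gamma(d0/2).
    """
    if np.any(np.asarray(sigma_sq) <= 0):
        raise ValueError("sigma_sq must be positive")
    a = hp.d0 / 2.0
    b = hp.d0 * hp.s0**2 / 2.0
    return a * np.log(b) - (a + 1.0) * np.log(sigma_sq) - b / sigma_sq - gammaln(a)
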