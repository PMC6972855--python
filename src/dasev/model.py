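"""Point-mass + left-censored lognormal mixture density and likelihood.

For feature *k* and sample *i*, the observed abundance Y_ik is zero with
probability p_ik (a biological point mass), otherwise log Y_ik is drawn
from Normal(mu_ik, sigma_k^2) left-censored at the log detection limit
lambda_k, so draws below the limit are also recorded as zero (technical
point masses).  The density of one observation is therefore

    P(Y = 0)      = p + (1 - p) * Phi((lambda - mu) / sigma)
    f(y), y > 0   = (1 - p) * phi((log y - mu) / sigma) / sigma

with a logistic link logit(p_ik) = X_i' gamma_k and a linear link
mu_ik = X_i' beta_k.  The constant 1/y Jacobian of the log transform is
omitted from the likelihood: it is free of all parameters, so it cancels
in every maximization and every likelihood-ratio statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "FeatureParams",
    "LinkValues",
    "LINK_CLAMP",
    "link_eval",
    "pmv_probability",
    "log_density",
    "feature_loglik",
    "loglik_and_grad",
]

#: linear predictors of the logistic link are clamped to this magnitude
#: before exponentiation, keeping p in (0, 1) near separation
LINK_CLAMP = 30.0

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class FeatureParams:
    """Per-feature parameters: logistic (gamma), mean (beta), and sigma."""

    gamma: np.ndarray
    beta: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.sigma = float(self.sigma)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def theta(self) -> np.ndarray:
        """Stacked coefficient vector (gamma, beta)."""
        return np.concatenate([self.gamma, self.beta])


@dataclass
class LinkValues:
    """Per-sample BPMV probabilities and non-BPMV log-means."""

    p: np.ndarray
    mu: np.ndarray


def link_eval(params: FeatureParams, design) -> LinkValues:
    """Evaluate both link models on every sample of the design.

    The logistic linear predictor is clamped at +/-LINK_CLAMP so that p
    stays strictly inside (0, 1) even for degenerate coefficient values.
    """
    X = np.asarray(getattr(design, "matrix", design), dtype=float)
    if X.shape[1] != params.gamma.size or X.shape[1] != params.beta.size:
        raise ValueError(
            f"design has {X.shape[1]} columns but gamma/beta have "
            f"{params.gamma.size}/{params.beta.size} coefficients"
        )
    eta = np.clip(X @ params.gamma, -LINK_CLAMP, LINK_CLAMP)
    return LinkValues(p=expit(eta), mu=X @ params.beta)


def pmv_probability(p, mu, sigma, lam):
    """Total probability of observing a zero: BPMV mass plus censored tail.

    Returns p + (1 - p) * Phi((lambda - mu) / sigma).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return p + (1.0 - p) * ndtr((np.asarray(lam) - np.asarray(mu)) / sigma)


def log_density(y: float, p: float, mu: float, sigma: float, lam: float) -> float:
    """Log mixture density of a single observation.

    For y = 0 the PMV branch log[p + (1-p) Phi((lam-mu)/sigma)]; for y > 0
    the censored-lognormal branch on the log scale (Jacobian omitted).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if y < 0:
        raise ValueError("abundances must be non-negative")
    if y == 0:
        return float(np.log(pmv_probability(p, mu, sigma, lam)))
    r = (np.log(y) - mu) / sigma
    return float(np.log1p(-p) - 0.5 * r * r - _LOG_SQRT_2PI - np.log(sigma))


def _loglik_terms(logy, pmv, eta, mu, sigma, lam):
    """Per-sample log-likelihood contributions, vectorized.

    ``logy`` holds log abundances for non-PMV samples (arbitrary where
    ``pmv`` is True).  Uses log_ndtr-based stable forms.
    """
    p = expit(eta)
    z = (lam - mu) / sigma
    out = np.empty_like(mu)
    if pmv.any():
        # log(p + (1-p) Phi(z)) with both addends computed in log space
        with np.errstate(divide="ignore"):
            a = np.log(p[pmv])
        b = np.log1p(-p[pmv]) + log_ndtr(z[pmv])
        out[pmv] = np.logaddexp(a, b)
    obs = ~pmv
    if obs.any():
        r = (logy[obs] - mu[obs]) / sigma
        out[obs] = np.log1p(-p[obs]) - 0.5 * r * r - _LOG_SQRT_2PI - np.log(sigma)
    return out


def feature_loglik(params: FeatureParams, design, feature_values, lam: float) -> float:
    """Log-likelihood of one feature: sum of per-sample mixture log-densities."""
    X = np.asarray(getattr(design, "matrix", design), dtype=float)
    y = np.asarray(feature_values, dtype=float)
    eta = np.clip(X @ params.gamma, -LINK_CLAMP, LINK_CLAMP)
    mu = X @ params.beta
    pmv = y == 0
    logy = np.where(pmv, 0.0, np.log(np.where(pmv, 1.0, y)))
    ll = float(_loglik_terms(logy, pmv, eta, mu, params.sigma, lam).sum())
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite log-likelihood at gamma={params.gamma}, beta={params.beta}, "
            f"sigma={params.sigma}, lambda={lam}"
        )
    return ll


def loglik_and_grad(theta, X, logy, pmv, sigma, lam):
    """Log-likelihood and its gradient with respect to theta = (gamma, beta).

    Used by the coefficient maximization step; sigma is held fixed.  The
    gradient of the clamped logistic link uses the unclamped p(1-p) factor,
    which vanishes smoothly in the saturated regime.
    """
    k = X.shape[1]
    gamma, beta = theta[:k], theta[k:]
    eta = np.clip(X @ gamma, -LINK_CLAMP, LINK_CLAMP)
    mu = X @ beta
    p = expit(eta)
    ll = float(_loglik_terms(logy, pmv, eta, mu, sigma, lam).sum())

    deta = np.empty_like(mu)
    dmu = np.empty_like(mu)
    if pmv.any():
        z = (lam - mu[pmv]) / sigma
        Phi = ndtr(z)
        phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        denom = p[pmv] + (1.0 - p[pmv]) * Phi
        deta[pmv] = (1.0 - Phi) * p[pmv] * (1.0 - p[pmv]) / denom
        dmu[pmv] = -(1.0 - p[pmv]) * phi / (sigma * denom)
    obs = ~pmv
    if obs.any():
        deta[obs] = -p[obs]
        dmu[obs] = (logy[obs] - mu[obs]) / sigma**2
    grad = np.concatenate([X.T @ deta, X.T @ dmu])
    return ll, grad
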