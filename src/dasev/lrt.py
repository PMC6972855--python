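"""Likelihood-ratio tests and FDR adjustment across features.

Three null hypotheses per covariate j:

* ``M`` — beta_j = 0: no effect on the mean of non-BPMV log abundance
  (chi-square, 1 df);
* ``P`` — gamma_j = 0: no effect on the BPMV proportion (1 df);
* ``B`` — both coefficients zero (2 df).

The unconstrained model is fitted first; sigma is then *fixed* at its
unconstrained estimate sigma_tilde and the constrained coefficients are
refitted at that sigma, so the constrained parameter space is exactly
nested in the unconstrained one and the statistic
2 (loglik_full - loglik_null) is non-negative by construction.
Benjamini-Hochberg q-values are computed across all features whose fits
produced finite p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .data import (
    AbundanceMatrix,
    DesignMatrix,
    detection_limits,
    filter_features,
)
from .fit import FitConfig, FitResult, fit_feature, maximize_theta
from .model import feature_loglik
from .prior import (
    PriorHyperparams,
    estimate_hyperparameters,
    rough_sigma,
    select_prior_features,
)

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "lrt_feature", "bh_adjust", "estimate_prior", "run_analysis"]

_HYPOTHESES = {"M": 1, "P": 1, "B": 2}

#: negative LRT statistics larger than this magnitude indicate optimizer
#: failure rather than rounding and raise instead of being clipped
_LRT_SLACK = 1e-8


@dataclass
class TestResult:
    """One feature's likelihood-ratio test."""

    feature_id: str
    hypothesis: str
    covariate_index: int
    lrt_stat: float
    df: int
    p_value: float
    beta_j: float
    gamma_j: float
    sigma_tilde: float
    loglik_full: float
    loglik_null: float
    converged: bool
    q_value: float = np.nan


def lrt_feature(
    feature_values,
    design: DesignMatrix,
    hp: PriorHyperparams | None,
    lam: float,
    hypothesis: str = "M",
    j: int = 1,
    config: FitConfig | None = None,
    feature_id: str = "",
    sigma_init: float | None = None,
    full_fit: FitResult | None = None,
) -> TestResult:
    """Likelihood-ratio test of one feature for covariate ``j``.

    Fits the unconstrained model, freezes sigma at sigma_tilde, refits the
    coefficients under the null constraint, and refers
    2 (loglik_full - loglik_null) to chi-square with 1 df (M, P) or
    2 df (B).
    """
    if hypothesis not in _HYPOTHESES:
        raise ValueError(f"hypothesis must be one of {sorted(_HYPOTHESES)}")
    if j < 1 or j >= design.n_params:
        raise ValueError(f"covariate index {j} must address a non-intercept column")
    config = config or FitConfig()
    k = design.n_params
    fit = full_fit if full_fit is not None else fit_feature(
        feature_values, design, hp, lam, config=config, sigma_init=sigma_init
    )
    sigma = fit.sigma_tilde
    # re-polish the unconstrained coefficients at the final sigma so the
    # full and null likelihoods are maximized at the identical sigma
    theta_full = maximize_theta(feature_values, design, sigma, lam,
                                init=fit.params, config=config)
    ll_full = feature_loglik(theta_full, design, feature_values, lam)

    constrained = {"M": (k + j,), "P": (j,), "B": (j, k + j)}[hypothesis]
    theta_null = maximize_theta(feature_values, design, sigma, lam,
                                init=theta_full, config=config,
                                fixed_zero=constrained)
    ll_null = feature_loglik(theta_null, design, feature_values, lam)
    if ll_null > ll_full:
        # the constrained search escaped a premature stop of the full fit;
        # the null optimum is feasible for the full model, so restart there
        theta_full = maximize_theta(feature_values, design, sigma, lam,
                                    init=theta_null, config=config)
        ll_full = max(ll_full, feature_loglik(theta_full, design, feature_values, lam))

    stat = 2.0 * (ll_full - ll_null)
    if stat < -_LRT_SLACK * (1.0 + abs(ll_full)):
        raise FloatingPointError(
            f"nesting violated for feature {feature_id!r}: LRT = {stat}"
        )
    stat = max(stat, 0.0)
    df = _HYPOTHESES[hypothesis]
    return TestResult(
        feature_id=feature_id,
        hypothesis=hypothesis,
        covariate_index=j,
        lrt_stat=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
        beta_j=float(theta_full.beta[j]),
        gamma_j=float(theta_full.gamma[j]),
        sigma_tilde=float(sigma),
        loglik_full=float(ll_full),
        loglik_null=float(ll_null),
        converged=bool(fit.converged),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_prior(
    matrix: AbundanceMatrix, lambdas: np.ndarray | None = None
) -> PriorHyperparams:
    """Fit the shared inverse-gamma prior from rough per-feature estimates."""
    if lambdas is None:
        lambdas = detection_limits(matrix)
    chosen = select_prior_features(matrix)
    idx = {f: i for i, f in enumerate(matrix.feature_ids)}
    sigma_hats = []
    for fid in chosen:
        i = idx[fid]
        if (matrix.values[i] > 0).sum() >= 2:
            sigma_hats.append(rough_sigma(matrix.values[i], lambdas[i]).sigma_hat)
    hp = estimate_hyperparameters(sigma_hats)
    return hp


def run_analysis(
    matrix: AbundanceMatrix,
    design: DesignMatrix,
    hypothesis: str = "M",
    mode: str = "dasev",
    config: FitConfig | None = None,
    j: int = 1,
    min_nonpmv: int = 3,
    epsilon: float = 0.1,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full differential-abundance pipeline for one hypothesis.

    filter -> detection limits -> prior (dasev mode) -> per-feature LRT
    -> Benjamini-Hochberg across all tested features.  Per-feature
    failures become flagged rows with NA p-values, excluded from the
    adjustment; the batch never aborts.  Deterministic given inputs.
    """
    config = config or FitConfig(mode=mode)
    if config.mode != mode:
        config = FitConfig(mode=mode, max_outer_iter=config.max_outer_iter,
                           max_inner_iter=config.max_inner_iter, tol=config.tol,
                           sigma2_floor_tlk=config.sigma2_floor_tlk,
                           clamp=config.clamp)
    report = filter_features(matrix, design, min_nonpmv=min_nonpmv)
    if not report.kept_feature_ids:
        logger.warning("no features pass the filters; returning empty table")
    kept = report.apply(matrix) if report.kept_feature_ids else None
    rows = []
    if kept is not None:
        lambdas = detection_limits(kept, epsilon)
        hp = estimate_prior(kept, lambdas) if mode == "dasev" else None
        for i, fid in enumerate(kept.feature_ids):
            y = kept.values[i]
            sig0 = rough_sigma(y, lambdas[i]).sigma_hat
            try:
                res = lrt_feature(y, design, hp, lambdas[i], hypothesis=hypothesis,
                                  j=j, config=config, feature_id=fid,
                                  sigma_init=sig0)
            except FloatingPointError as err:
                logger.warning("feature %s failed: %s", fid, err)
                res = TestResult(fid, hypothesis, j, np.nan, _HYPOTHESES[hypothesis],
                                 np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                                 False)
            rows.append(res)
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in rows],
            "beta_j": [r.beta_j for r in rows],
            "gamma_j": [r.gamma_j for r in rows],
            "log_fold_change": [r.beta_j for r in rows],
            "fold_change": [np.exp(r.beta_j) for r in rows],
            "sigma_tilde": [r.sigma_tilde for r in rows],
            "lrt_stat": [r.lrt_stat for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
            "converged": [r.converged for r in rows],
        }
    )
    q = np.full(len(df), np.nan)
    ok = np.isfinite(df["p_value"].to_numpy())
    if ok.any():
        q[ok] = bh_adjust(df.loc[ok, "p_value"].to_numpy())
    df["q_value"] = q
    df["significant"] = q <= fdr
    df.attrs.update(
        hypothesis=hypothesis, mode=mode, covariate_index=j, fdr=fdr,
        n_dropped=len(report.dropped), drop_reasons=dict(report.dropped),
    )
    return df
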