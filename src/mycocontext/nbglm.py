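"""Negative-binomial GLMs with log link and maximum-likelihood dispersion.

The NB2 parameterisation is used throughout: for mean mu and dispersion
theta > 0, Var(y) = mu + mu^2 / theta.  Coefficients are fitted by IRLS
(via statsmodels) for a fixed theta, alternating with one-dimensional
profile maximisation of the likelihood over log(theta) — the behaviour
of the classical ``glm.nb`` estimator.  The log-likelihood kernel is
shared with the ecogroup mixture model's E-step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

logger = logging.getLogger(__name__)

THETA_MIN, THETA_MAX = 1e-4, 1e8


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


class DegenerateResponseError(ValueError):
    """Response carries no information (e.g. all zeros)."""


def nb_log_likelihood(y, mu, theta, weights=None) -> float:
    """Exact NB2 log-likelihood, summed over observations.

    Computed in log space via gammaln; optional per-observation weights
    multiply each observation's contribution (used by the mixture
    M-step).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or theta <= 0:
        raise ValueError("mu and theta must be strictly positive")
    ll = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )
    if weights is not None:
        ll = ll * weights
    return float(np.sum(ll))


def _profile_theta(y, mu, weights=None, bounds=(THETA_MIN, THETA_MAX)) -> float:
    """Maximise the NB2 likelihood over theta for fixed means."""
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    res = minimize_scalar(
        lambda lt: -nb_log_likelihood(y, mu, np.exp(lt), weights),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


@dataclass
class NbGlmFit:
    """A fitted negative-binomial GLM.

    ``p`` counts the regression coefficients plus one for the estimated
    dispersion, and ``aic = -2*log_likelihood + 2*p`` holds exactly.
    """

    coefficients: pd.Series
    dispersion: float
    log_likelihood: float
    deviance: float
    null_deviance: float
    n: int
    p: int
    aic: float
    fitted_means: np.ndarray
    design_info: dict
    converged: bool
    bse: pd.Series = field(default=None, repr=False)
    pvalues: pd.Series = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        z = self.coefficients / self.bse
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": self.bse,
                "z": z,
                "p": self.pvalues,
            }
        )


def _as_design(design) -> pd.DataFrame:
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(
            np.asarray(design, dtype=float),
            columns=[f"x{i}" for i in range(np.asarray(design).shape[1])],
        )
    return design.astype(float)


def fit_nb_glm(
    y,
    design,
    offset=None,
    theta: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> NbGlmFit:
    """Fit an NB2 GLM with log link by alternating IRLS and profile ML.

    Parameters
    ----------
    y : array of non-negative integer counts.
    design : matrix with an intercept column (DataFrame preferred; the
        column names become coefficient names).
    offset : optional log-scale offset with coefficient fixed at 1.
    theta : if given, the dispersion is held fixed instead of estimated
        (useful for Poisson-limit checks); it then does not count as an
        estimated parameter.
    """
    design = _as_design(design)
    y = np.asarray(y, dtype=float)
    n, k = design.shape
    if len(y) != n:
        raise ValueError("length of y does not match design rows")
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        if len(offset) != n:
            raise ValueError("offset length does not match design rows")
    if np.all(y == 0):
        raise DegenerateResponseError("all responses are zero")
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < k:
        if n < k:
            raise SingularDesignError(
                f"design has more columns ({k}) than observations ({n})"
            )
        # name a minimal set of columns involved in the collinearity
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [
            design.columns[i]
            for i in range(len(diag))
            if diag[i] < 1e-8 * max(1.0, diag.max())
        ]
        raise SingularDesignError(
            f"design is rank deficient; collinear column(s): {bad}"
        )

    estimate_theta = theta is None
    if estimate_theta:
        m, v = y.mean(), y.var()
        theta = float(np.clip(m * m / max(v - m, 1e-8), 1e-2, 1e4))

    def _glm(th, start=None):
        fam = sm.families.NegativeBinomial(alpha=1.0 / th)
        model = sm.GLM(y, X, family=fam, offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(start_params=start, maxiter=100, tol=1e-10)

    res = _glm(theta)
    ll = nb_log_likelihood(y, res.fittedvalues, theta)
    converged = not estimate_theta
    if estimate_theta:
        for _ in range(max_iter):
            theta_new = _profile_theta(y, res.fittedvalues)
            res = _glm(theta_new, start=res.params)
            ll_new = nb_log_likelihood(y, res.fittedvalues, theta_new)
            # secondary stop on a stable dispersion guards against
            # dithering when theta sits at the Poisson-limit boundary
            if (
                abs(ll_new - ll) < tol * (abs(ll) + tol)
                or abs(np.log(theta_new / theta)) < 1e-7
            ):
                theta, ll = theta_new, ll_new
                converged = True
                break
            theta, ll = theta_new, ll_new
        if not converged:
            logger.warning("fit_nb_glm did not converge in %d iterations", max_iter)

    mu = np.asarray(res.fittedvalues)
    deviance = float(res.deviance)
    # null model: intercept only, same offset, same theta (glm.nb convention)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_res = sm.GLM(
            y,
            np.ones((n, 1)),
            family=sm.families.NegativeBinomial(alpha=1.0 / theta),
            offset=offset,
        ).fit()
    null_deviance = float(null_res.deviance)

    p = k + (1 if estimate_theta else 0)
    aic = -2.0 * ll + 2.0 * p
    names = list(design.columns)
    return NbGlmFit(
        coefficients=pd.Series(res.params, index=names),
        dispersion=float(theta),
        log_likelihood=float(ll),
        deviance=max(deviance, 0.0),
        null_deviance=max(null_deviance, 0.0),
        n=n,
        p=p,
        aic=float(aic),
        fitted_means=mu,
        design_info={"columns": names, "has_offset": offset is not None},
        converged=bool(converged),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
    )


def predict_mean(fit: NbGlmFit, new_design, new_offset=None) -> np.ndarray:
    """exp(X beta + offset) on new data; columns must match the fit."""
    new_design = _as_design(new_design)
    if list(new_design.columns) != fit.design_info["columns"]:
        raise ValueError(
            "design columns do not match the fitted model: "
            f"{list(new_design.columns)} vs {fit.design_info['columns']}"
        )
    eta = new_design.to_numpy() @ fit.coefficients.to_numpy()
    if new_offset is not None:
        eta = eta + np.asarray(new_offset, dtype=float)
    return np.exp(eta)


def adjusted_d2(fit: NbGlmFit) -> float:
    """Adjusted deviance explained, 1 - ((n-1)/(n-p)) * (1 - D^2).

    D^2 = 1 - deviance/null_deviance is the GLM analogue of R^2; the
    adjustment penalises parameter count and the result can be negative
    when a model explains less than its parameters warrant.
    """
    if fit.null_deviance <= 0:
        raise ValueError("null deviance must be positive")
    if fit.n <= fit.p:
        raise ValueError("adjusted D2 undefined for n <= p")
    d2 = 1.0 - fit.deviance / fit.null_deviance
    return 1.0 - ((fit.n - 1) / (fit.n - fit.p)) * (1.0 - d2)


def format_adjusted_d2(value: float, digits: int = 2) -> str:
    """Render negative adjusted D2 as "0 (value)" in comparison tables."""
    if value < 0:
        return f"0 ({value:.{digits}f})"
    return f"{value:.{digits}f}"


def fit_nb_weighted(y, X, weights, offset=None, theta=None, start=None):
    """Weighted NB fit used by the mixture M-step.

    Maximises ``sum_i w_i * loglik_i`` over beta for fixed theta via
    statsmodels var_weights, then (if theta is None) profiles theta
    under the same weights.  Returns (beta, theta, fitted_eta_without_offset).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if theta is None:
        theta = 1.0
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=fam, offset=offset, var_weights=np.maximum(w, 1e-12)).fit(
            start_params=start, maxiter=50, tol=1e-9
        )
    beta = np.asarray(res.params)
    mu = np.asarray(res.fittedvalues)
    new_theta = _profile_theta(y, mu, weights=w, bounds=(1e-3, 1e6))
    return beta, new_theta
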