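"""Ecogroups: a finite mixture of negative-binomial regressions.

OTUs are clustered by their modelled response to the environment, not
by their abundance: each mixture component ("ecogroup", the species
archetype of joint species modelling) owns a shared coefficient vector
beta_g over the covariates and a dispersion theta_g, while every OTU
keeps its own intercept alpha_i so that common and rare OTUs with the
same response shape land in the same group.  For OTU i with counts
y_i1..y_in over samples with covariate rows x_j,

    L(Theta) = prod_i sum_g pi_g prod_j NB(y_ij; exp(alpha_i + x_j' beta_g), theta_g)

is maximised by EM.  The E-step computes membership probabilities
tau_ig in log space (log-sum-exp); the M-step updates pi by the tau
means, each (beta_g, theta_g) by a tau-weighted NB regression, and the
per-OTU intercepts by vectorised Newton steps.  Each partial update is
accepted only if it improves its own objective, so the observed-data
log-likelihood never decreases (generalised EM).

The model is meant for a rarefied table (equal library sizes), in which
case no offset is needed; an offset argument exists for unrarefied use.
OTUs with zero counts after rarefaction are dropped before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .nbglm import fit_nb_glm, fit_nb_weighted

logger = logging.getLogger(__name__)


@dataclass
class EcogroupModel:
    """Fitted mixture: pi (G), beta (G x p), theta (G), per-OTU alpha, tau."""

    G: int
    pi: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray
    log_likelihood: float
    converged: bool
    otu_ids: list[str]
    term_names: list[str]
    n_starts: int
    seed: int
    tolerance: float
    trace: list[float] = field(default_factory=list, repr=False)


@dataclass
class EcogroupAssignment:
    """otu_id -> (ecogroup index, membership probability of that group)."""

    table: pd.DataFrame  # otu_id, ecogroup, probability


def _component_loglik(Y, X, alpha, beta, theta, offset=None):
    """n_otu x G matrix of per-OTU log-likelihoods under each group."""
    n_otu, _ = Y.shape
    G = beta.shape[0]
    out = np.empty((n_otu, G))
    from scipy.special import gammaln

    for g in range(G):
        eta = alpha[:, None] + (X @ beta[g])[None, :]
        if offset is not None:
            eta = eta + offset[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        th = theta[g]
        ll = (
            gammaln(Y + th)
            - gammaln(th)
            - gammaln(Y + 1.0)
            + th * np.log(th / (th + mu))
            + Y * np.log(mu / (th + mu))
        )
        out[:, g] = ll.sum(axis=1)
    return out


def _update_alpha(Y, X, alpha, beta, theta, tau, offset=None, n_newton=4):
    """Vectorised Newton updates of per-OTU intercepts.

    Maximises, independently per OTU i, the tau-weighted expected
    complete log-likelihood in alpha_i; steps that do not improve the
    objective are rejected per OTU (step-halving once, then keep old).
    """
    n_otu = Y.shape[0]
    G = beta.shape[0]
    eta_g = np.stack([(X @ beta[g]) for g in range(G)])  # G x n_samples
    if offset is not None:
        eta_g = eta_g + offset[None, :]

    def obj_grad_hess(a):
        obj = np.zeros(n_otu)
        grad = np.zeros(n_otu)
        hess = np.zeros(n_otu)
        from scipy.special import gammaln

        for g in range(G):
            mu = np.exp(np.clip(a[:, None] + eta_g[g][None, :], -30.0, 30.0))
            th = theta[g]
            ll = (
                gammaln(Y + th) - gammaln(th) - gammaln(Y + 1.0)
                + th * np.log(th / (th + mu))
                + Y * np.log(mu / (th + mu))
            ).sum(axis=1)
            w = tau[:, g]
            obj += w * ll
            grad += w * ((Y - mu) * th / (th + mu)).sum(axis=1)
            hess -= w * (mu * th * (th + Y) / (th + mu) ** 2).sum(axis=1)
        return obj, grad, hess

    obj, grad, hess = obj_grad_hess(alpha)
    for _ in range(n_newton):
        step = grad / np.where(hess < -1e-12, -hess, 1.0)
        step = np.clip(step, -2.0, 2.0)
        cand = alpha + step
        obj_c, grad_c, hess_c = obj_grad_hess(cand)
        worse = obj_c < obj
        if worse.any():  # halve once, then give up on those OTUs
            cand[worse] = alpha[worse] + 0.5 * step[worse]
            obj_c, grad_c, hess_c = obj_grad_hess(cand)
            still = obj_c < obj
            cand[still] = alpha[still]
            obj_c = np.where(still, obj, obj_c)
        improved = cand != alpha
        alpha, obj = cand, obj_c
        grad, hess = grad_c, hess_c
        if not improved.any():
            break
    return alpha


def _m_step(Y, X, alpha, beta, theta, tau, offset=None):
    """Update (beta_g, theta_g) by tau-weighted NB regression, then alpha."""
    n_otu, n_samp = Y.shape
    G = beta.shape[0]
    y_flat = Y.ravel()
    X_tiled = np.tile(X, (n_otu, 1))
    off_alpha = np.repeat(alpha, n_samp)
    if offset is not None:
        off_alpha = off_alpha + np.tile(offset, n_otu)
    for g in range(G):
        w = np.repeat(tau[:, g], n_samp)
        if w.sum() < 1e-8:
            continue  # empty component: keep previous parameters
        try:
            beta_g, theta_g = fit_nb_weighted(
                y_flat, X_tiled, w, offset=off_alpha, theta=theta[g], start=beta[g]
            )
            beta[g], theta[g] = beta_g, theta_g
        except Exception as exc:
            logger.warning("M-step update failed for group %d: %s", g, exc)
    alpha = _update_alpha(Y, X, alpha, beta, theta, tau, offset=offset)
    return alpha, beta, theta


def _em(Y, X, pi, alpha, beta, theta, offset, tol, max_iter):
    trace = []
    ll_old = -np.inf
    converged = False
    tau = None
    for _ in range(max_iter):
        logf = _component_loglik(Y, X, alpha, beta, theta, offset)
        logpost = np.log(np.maximum(pi, 1e-300))[None, :] + logf
        norm = logsumexp(logpost, axis=1)
        ll = float(norm.sum())
        tau = np.exp(logpost - norm[:, None])
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol * (abs(ll) + tol):
            converged = True
            break
        ll_old = ll
        pi = tau.mean(axis=0)
        alpha, beta, theta = _m_step(Y, X, alpha, beta, theta, tau, offset)
    return pi, alpha, beta, theta, tau, trace, converged


def _kmeans_start(Y, X, G, rng):
    """Deterministic start: k-means on per-OTU independent NB slopes."""
    n_otu = Y.shape[0]
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    coefs = np.zeros((n_otu, X.shape[1]))
    for i in range(n_otu):
        try:
            fit = fit_nb_glm(Y[i], pd.DataFrame(Xi), tol=1e-6, max_iter=25)
            coefs[i] = fit.coefficients.to_numpy()[1:]
        except Exception:
            coefs[i] = 0.0
    km = KMeans(n_clusters=G, n_init=5, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(coefs)
    tau = np.full((n_otu, G), 0.05 / max(G - 1, 1))
    tau[np.arange(n_otu), labels] = 0.95
    if G == 1:
        tau[:] = 1.0
    return tau / tau.sum(axis=1, keepdims=True)


def fit_archetype_mixture(
    rarefied: pd.DataFrame,
    design: pd.DataFrame,
    G: int,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    offset=None,
) -> EcogroupModel:
    """Fit the G-component NB regression mixture to a rarefied OTU table.

    Parameters
    ----------
    rarefied : samples x OTUs count table (equal row sums after
        rarefaction; unequal sums require ``offset``).
    design : samples x covariates matrix WITHOUT an intercept column
        (per-OTU intercepts play that role).  Standardising continuous
        covariates is recommended so coefficient profiles are
        comparable across terms.
    G : number of ecogroups (the study workflow uses the number of
        fungal functional groups, 6).
    n_starts : start 1 is k-means on per-OTU NB slopes; the rest draw
        random responsibilities.  The best final log-likelihood wins.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    counts = rarefied.loc[:, rarefied.sum(axis=0) > 0]
    dropped = rarefied.shape[1] - counts.shape[1]
    if dropped:
        logger.info("dropping %d all-zero OTU(s) before mixture fit", dropped)
    Y = counts.to_numpy(dtype=float).T  # n_otu x n_samples
    n_otu, n_samp = Y.shape
    if G > n_otu:
        raise ValueError(f"G={G} exceeds the number of OTUs ({n_otu})")
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    terms = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(X.shape[1])
    ]
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
    rng = np.random.default_rng(seed)

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            tau0 = _kmeans_start(Y, X, G, rng)
        else:
            tau0 = rng.uniform(0.05, 1.0, size=(n_otu, G))
            tau0 /= tau0.sum(axis=1, keepdims=True)
        # initial M-step from the responsibilities
        alpha = np.log(Y.mean(axis=1) + 0.5)
        if offset is not None:
            alpha = alpha - np.mean(offset)
        beta = np.zeros((G, X.shape[1]))
        theta = np.ones(G)
        pi = tau0.mean(axis=0)
        alpha, beta, theta = _m_step(Y, X, alpha, beta, theta, tau0, offset)
        pi, alpha, beta, theta, tau, trace, conv = _em(
            Y, X, pi, alpha, beta, theta, offset, tol, max_iter
        )
        if best is None or trace[-1] > best["ll"]:
            best = dict(pi=pi, alpha=alpha, beta=beta, theta=theta, tau=tau,
                        trace=trace, conv=conv, ll=trace[-1])

    # canonical order: descending mixing proportion
    order = np.argsort(-best["pi"], kind="stable")
    if not best["conv"]:
        logger.warning("no EM start converged; returning best iterate")
    return EcogroupModel(
        G=G,
        pi=best["pi"][order],
        beta=best["beta"][order],
        theta=best["theta"][order],
        alpha=best["alpha"],
        tau=best["tau"][:, order],
        log_likelihood=float(best["ll"]),
        converged=bool(best["conv"]),
        otu_ids=list(counts.columns),
        term_names=terms,
        n_starts=n_starts,
        seed=seed,
        tolerance=tol,
        trace=best["trace"],
    )


def responsibilities(model: EcogroupModel, rarefied: pd.DataFrame, design, offset=None) -> np.ndarray:
    """Recompute the membership matrix tau from the model parameters."""
    counts = rarefied.loc[:, model.otu_ids]
    Y = counts.to_numpy(dtype=float).T
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    logf = _component_loglik(
        Y, X, model.alpha, model.beta, model.theta,
        None if offset is None else np.asarray(offset, float),
    )
    logpost = np.log(np.maximum(model.pi, 1e-300))[None, :] + logf
    return np.exp(logpost - logsumexp(logpost, axis=1)[:, None])


def assign_ecogroups(model: EcogroupModel) -> EcogroupAssignment:
    """Hard assignment to the highest-membership group (ties -> lowest index)."""
    idx = np.argmax(model.tau, axis=1)
    prob = model.tau[np.arange(len(idx)), idx]
    n_ties = int(np.sum(np.isclose(model.tau, prob[:, None]).sum(axis=1) > 1))
    if n_ties:
        logger.info("assign_ecogroups: %d tie(s) broken toward the lowest index", n_ties)
    return EcogroupAssignment(
        table=pd.DataFrame(
            {"otu_id": model.otu_ids, "ecogroup": idx + 1, "probability": prob}
        )
    )


def coefficient_profiles(model: EcogroupModel) -> pd.DataFrame:
    """Long-format (ecogroup, term, coefficient) table for profile plots.

    Profiles from abiotic and biotic fits carry independent group
    numberings; a coefficient near 0 means little modelled relationship
    between the term and the group's abundance.
    """
    rows = []
    for g in range(model.G):
        for t, term in enumerate(model.term_names):
            rows.append(
                {"ecogroup": g + 1, "term": term, "coefficient": model.beta[g, t]}
            )
    return pd.DataFrame(rows)


def mixture_design(samples: pd.DataFrame, vset, standardize: bool = True) -> pd.DataFrame:
    """Covariate matrix for the mixture (no intercept, z-scored continuous)."""
    from .design import ScaleSpec, build_design

    lib = pd.Series(1.0, index=samples["sample_id"].to_numpy())
    X, _ = build_design(samples, lib, vset, ScaleSpec("overall"), mode="abundance")
    X = X.drop(columns=["intercept"])
    X = X.loc[:, [c for c in X.columns if not c.startswith("site[")]]
    if standardize:
        for c in X.columns:
            col = X[c].to_numpy(dtype=float)
            if len(np.unique(col)) > 2:
                X[c] = (col - col.mean()) / col.std()
    return X
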