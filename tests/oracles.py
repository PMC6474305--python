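"""Independent oracles used to freeze expected values.

The grid oracle maximises the exact NB2 log-likelihood by iterative
grid refinement over the regression coefficients and log(theta) —
no IRLS, no profile steps — so it is an independent check on the
fitting path.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def nb2_loglik(y, mu, theta):
    y = np.asarray(y, dtype=float)
    return np.sum(
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu)),
        axis=-1,
    )


def grid_mle(y, X, n_refine=8, width0=4.0, n_points=13):
    """Joint MLE of (beta, log theta) by shrinking-grid search.

    Starts centred on (log mean(y), 0, ..., log theta_moment) with a
    wide window, then repeatedly re-centres on the best grid point and
    shrinks the window.  Returns (beta, theta, loglik).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    m, v = y.mean(), y.var()
    centre = np.zeros(k + 1)
    centre[0] = np.log(max(m, 0.1))
    centre[-1] = np.log(np.clip(m * m / max(v - m, 1e-3), 1e-2, 1e3))
    width = width0
    best = None
    for _ in range(n_refine):
        axes = [np.linspace(c - width, c + width, n_points) for c in centre]
        grid = np.array(list(itertools.product(*axes)))
        beta = grid[:, :k]
        theta = np.exp(grid[:, k])
        mu = np.exp(beta @ X.T)  # (n_grid, n_obs)
        ll = nb2_loglik(y[None, :], mu, theta[:, None])
        i = int(np.argmax(ll))
        centre = grid[i]
        best = (grid[i, :k].copy(), float(np.exp(grid[i, k])), float(ll[i]))
        width = width * 2.2 / (n_points - 1)  # keep neighbours of the best point
    return best


if __name__ == "__main__":
    # regenerate the frozen expectations used in the oracle-equivalence test
    from test_acceptance import ORACLE_DATASETS  # noqa: F401

    for name, (y, X) in ORACLE_DATASETS.items():
        b, t, ll = grid_mle(y, X)
        print(name, np.round(b, 5), round(t, 5), round(ll, 5))
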