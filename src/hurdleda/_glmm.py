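"""Random-intercept logistic regression with observation weights.

The marginal likelihood integrates the random intercept out with
Gauss-Hermite quadrature (exact as the node count grows; 25 nodes is
ample for a single scalar intercept). Observation weights enter the
conditional log-likelihood multiplicatively, which is what the
prevalence data-augmentation scheme requires and what off-the-shelf
GLMM fitters generally do not support.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import logsumexp


def _neg_marginal_loglik(params, y, X, w, group_idx, n_groups, nodes, log_node_w):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta0 = X @ beta
    # conditional loglik per observation per node, summed within groups
    # nodes scaled for N(0, sigma^2): u_q = sqrt(2) * sigma * t_q
    u = np.sqrt(2.0) * sigma * nodes  # (Q,)
    eta = eta0[None, :] + u[:, None]  # (Q, N)
    # stable bernoulli loglik: y*eta - log(1 + exp(eta))
    ll_obs = w[None, :] * (y[None, :] * eta - np.logaddexp(0.0, eta))
    # sum over observations within each group, per node
    ll_group = np.zeros((len(nodes), n_groups))
    for q in range(len(nodes)):
        ll_group[q] = np.bincount(group_idx, weights=ll_obs[q], minlength=n_groups)
    # log integral per group: logsumexp over nodes of (log w_q - 0.5*log(pi) + ll)
    log_integrand = log_node_w[:, None] - 0.5 * np.log(np.pi) + ll_group
    return -float(np.sum(logsumexp(log_integrand, axis=0)))


def _numeric_hessian(f, x, eps=1e-4):
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def fit_weighted_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray,
    start_beta: np.ndarray | None = None,
    n_nodes: int = 25,
    tol: float = 1e-8,
    maxiter: int = 200,
):
    """Fit logit(P(y=1)) = X beta + u_group, u ~ N(0, sigma^2).

    Returns ``(beta, se_beta, sigma, converged, loglik)``. Standard
    errors come from the inverse numerical Hessian of the negative
    marginal log-likelihood at the optimum (Wald).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    uniq, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(uniq)
    k = X.shape[1]

    nodes, node_w = hermgauss(n_nodes)
    log_node_w = np.log(node_w)

    if start_beta is None:
        start_beta = np.zeros(k)
    x0 = np.concatenate([start_beta, [np.log(0.5)]])
    args = (y, X, w, group_idx, n_groups, nodes, log_node_w)

    res = optimize.minimize(
        _neg_marginal_loglik,
        x0,
        args=args,
        method="L-BFGS-B",
        bounds=[(None, None)] * k + [(-8.0, 4.0)],
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-6},
    )
    params = res.x
    f = lambda p: _neg_marginal_loglik(p, *args)
    try:
        H = _numeric_hessian(f, params)
        cov = np.linalg.inv(H)
        se_beta = np.sqrt(np.clip(np.diag(cov)[:k], 0, np.inf))
        cov_beta = cov[:k, :k]
        ok = np.all(np.isfinite(se_beta))
    except np.linalg.LinAlgError:
        se_beta = np.full(k, np.nan)
        cov_beta = np.full((k, k), np.nan)
        ok = False
    converged = bool(res.success) and ok
    return {
        "beta": params[:k],
        "se": se_beta,
        "cov": cov_beta,
        "sigma": float(np.exp(params[-1])),
        "converged": converged,
        "loglik": -float(res.fun),
    }
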