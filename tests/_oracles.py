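"""Independent reference computations used to check the main code paths."""

import numpy as np
from scipy.optimize import minimize


def mle_by_completion(S, edges, m_free_tol=1e-10):
    """Constrained Gaussian MLE via the max-determinant completion property.

    The MLE covariance under a graphical zero-pattern is the unique
    positive-definite matrix that (a) agrees with S on the diagonal and on
    every edge and (b) maximizes the determinant over the free (non-edge)
    positions.  This solves (b) numerically with a generic optimizer —
    completely independent of the proportional-scaling path it is used to
    check.
    """
    S = np.asarray(S, dtype=float)
    N = S.shape[0]
    edge_set = {(min(e), max(e)) for e in edges}
    free = [
        (i, j)
        for i in range(N)
        for j in range(i + 1, N)
        if (i, j) not in edge_set
    ]
    base = S.copy()
    for (i, j) in free:
        base[i, j] = base[j, i] = 0.0
    if not free:
        return S.copy()

    def build(y):
        M = base.copy()
        for (i, j), v in zip(free, y):
            M[i, j] = M[j, i] = v
        return M

    def neg_logdet(y):
        sign, ld = np.linalg.slogdet(build(y))
        if sign <= 0:
            return 1e6
        return -ld

    y0 = np.zeros(len(free))
    res = minimize(neg_logdet, y0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000,
                            "maxfev": 40000})
    res = minimize(neg_logdet, res.x, method="Powell",
                   options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000})
    return build(res.x)


def mle_by_loglik_opt(S, edges):
    """Constrained Gaussian MLE by direct likelihood maximization.

    Numerically maximizes ``logdet K - tr(S K)`` over the free entries of the
    precision matrix K (diagonal plus the graph's edges; structural zeros
    elsewhere) with a generic optimizer.  Returns the fitted covariance.
    """
    S = np.asarray(S, dtype=float)
    N = S.shape[0]
    edge_list = sorted({(min(e), max(e)) for e in edges})
    n_free = N + len(edge_list)

    def build_K(theta):
        K = np.zeros((N, N))
        K[np.diag_indices(N)] = theta[:N]
        for q, (i, j) in enumerate(edge_list):
            K[i, j] = K[j, i] = theta[N + q]
        return K

    def neg_loglik(theta):
        K = build_K(theta)
        sign, ld = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e8
        return -(ld - np.trace(S @ K))

    theta0 = np.concatenate([1.0 / np.diag(S), np.zeros(len(edge_list))])
    res = minimize(neg_loglik, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14,
                            "maxiter": 50000, "maxfev": 100000})
    res = minimize(neg_loglik, res.x, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10000})
    K = build_K(res.x)
    return np.linalg.inv(K)


def gaussian_loglik(S, Sigma, n_obs):
    """Up-to-constant Gaussian log-likelihood of a fitted covariance."""
    K = np.linalg.inv(Sigma)
    sign, ld = np.linalg.slogdet(Sigma)
    assert sign > 0
    return -0.5 * n_obs * (ld + np.trace(S @ K))
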