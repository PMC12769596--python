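"""Independent brute-force references for the analysis engines.

Everything here works from the full per-cluster covariance matrices with
generic dense linear algebra and generic optimizers, deliberately avoiding
the Sherman-Morrison/profiling shortcuts used by the package.
"""

import numpy as np
from scipy import optimize


def split_clusters(X, y, groups):
    order = np.argsort(groups, kind="stable")
    X, y, groups = X[order], y[order], groups[order]
    out = []
    for gid in np.unique(groups):
        m = groups == gid
        out.append((X[m], y[m]))
    return out


def restricted_loglik(tau2, sigma2, clusters):
    """Restricted log-likelihood via dense per-cluster covariance matrices."""
    p = clusters[0][0].shape[1]
    n = sum(len(yi) for _, yi in clusters)
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    logdet_v = 0.0
    for Xi, yi in clusters:
        ni = len(yi)
        Vi = sigma2 * np.eye(ni) + tau2 * np.ones((ni, ni))
        sign, ld = np.linalg.slogdet(Vi)
        if sign <= 0:
            return -np.inf
        logdet_v += ld
        Vinv_X = np.linalg.solve(Vi, Xi)
        Vinv_y = np.linalg.solve(Vi, yi)
        A += Xi.T @ Vinv_X
        b += Xi.T @ Vinv_y
        q += float(yi @ Vinv_y)
    sign_a, logdet_a = np.linalg.slogdet(A)
    if sign_a <= 0:
        return -np.inf
    beta = np.linalg.solve(A, b)
    quad = q - float(b @ beta)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_a + quad)


def brute_force_reml(X, y, groups):
    """Maximize the restricted likelihood over (log tau2, log sigma2)."""
    clusters = split_clusters(X, y, groups)

    def neg(theta):
        return -restricted_loglik(np.exp(theta[0]), np.exp(theta[1]), clusters)

    best = None
    for start in ([-2.0, 0.0], [0.0, 0.0], [-8.0, 0.0]):
        res = optimize.minimize(
            neg, start, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau2, sigma2 = np.exp(best.x)
    # the boundary tau2 -> 0 may dominate any interior point
    res0 = optimize.minimize_scalar(
        lambda t: -restricted_loglik(0.0, np.exp(t), clusters),
        bounds=(-10, 10), method="bounded", options={"xatol": 1e-13},
    )
    if -res0.fun > -best.fun:
        tau2, sigma2 = 0.0, float(np.exp(res0.x))
    beta, _ = gls(X, y, groups, tau2=tau2, sigma2=sigma2)
    return {
        "tau2": tau2,
        "sigma2": sigma2,
        "beta": beta,
        "loglik": restricted_loglik(tau2, sigma2, clusters),
    }


def gls(X, y, groups, tau2=None, sigma2=None, alpha=None):
    """Closed-form GLS with a known compound-symmetry covariance.

    Either (tau2, sigma2) or an exchangeable correlation ``alpha`` (unit
    variance) specifies the per-cluster covariance.
    """
    clusters = split_clusters(X, y, groups)
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for Xi, yi in clusters:
        ni = len(yi)
        if alpha is not None:
            Vi = (1 - alpha) * np.eye(ni) + alpha * np.ones((ni, ni))
        else:
            Vi = sigma2 * np.eye(ni) + tau2 * np.ones((ni, ni))
        A += Xi.T @ np.linalg.solve(Vi, Xi)
        b += Xi.T @ np.linalg.solve(Vi, yi)
    beta = np.linalg.solve(A, b)
    return beta, np.linalg.inv(A)


def satterthwaite_oracle(X, y, groups, tau2, sigma2, contrast):
    """Satterthwaite df by Richardson-extrapolated central differences.

    Gradient of ``c' V_beta(theta) c`` and the observed-information Hessian
    are both taken on the dense-matrix restricted likelihood, at two step
    sizes combined by Richardson extrapolation.
    """
    clusters = split_clusters(X, y, groups)
    c = np.asarray(contrast, float)
    th = np.array([tau2, sigma2])

    def fval(theta):
        _, V = gls(X, y, groups, tau2=theta[0], sigma2=theta[1])
        return float(c @ V @ c)

    def grad(h):
        g = np.empty(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = h[i]
            g[i] = (fval(th + e) - fval(th - e)) / (2 * h[i])
        return g

    def hess(h):
        H = np.empty((2, 2))
        f0 = restricted_loglik(th[0], th[1], clusters)

        def f(t):
            return restricted_loglik(t[0], t[1], clusters)

        for i in range(2):
            for k in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ek = np.zeros(2); ek[k] = h[k]
                if i == k:
                    H[i, i] = (f(th + ei) - 2 * f0 + f(th - ei)) / h[i] ** 2
                else:
                    H[i, k] = H[k, i] = (
                        f(th + ei + ek) - f(th + ei - ek)
                        - f(th - ei + ek) + f(th - ei - ek)
                    ) / (4 * h[i] * h[k])
        return H

    h1 = 1e-4 * np.abs(th)
    # Richardson: R(h) = (4 R(h/2) - R(h)) / 3 for O(h^2) central schemes
    g = (4 * grad(h1 / 2) - grad(h1)) / 3
    H = (4 * hess(h1 / 2) - hess(h1)) / 3
    info = -H
    var_f = float(g @ np.linalg.solve(info, g))
    return 2.0 * fval(th) ** 2 / var_f
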