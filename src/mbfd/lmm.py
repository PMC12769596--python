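"""Random-intercept linear mixed models for MBFD data.

Three mean models are supported, all with an intercept and a linear period
trend:

* Model 1 (additive): exposure indicators ``x_a``, ``x_b``; the combined
  phase has both set to 1, so the AB effect is ``beta_a + beta_b``.
* Model 2 (interaction): adds the product ``x_a * x_b`` (coefficient
  ``beta_i``), relaxing additivity of the sequential combination.
* Model 3 (multi-arm): mutually exclusive phase indicators ``z_a``, ``z_b``,
  ``z_c``; the combined effect ``beta_c`` is estimated directly.

Estimation is restricted maximum likelihood (REML) under the compound-
symmetry covariance ``V_i = sigma^2 I + tau^2 11'`` per participant. The
REML criterion is profiled: for a fixed variance ratio
``lam = tau^2/sigma^2`` the GLS coefficients and ``sigma^2`` are closed form
(the Sherman-Morrison identity makes every per-participant inverse
rank-one-corrected), leaving a 1-D optimization over ``log lam``. Wald
t-tests use Satterthwaite degrees of freedom obtained by the delta method
from the inverse observed REML information of ``(tau^2, sigma^2)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "FitResult",
    "design_matrix",
    "RandomInterceptLMM",
    "fit_reml",
    "satterthwaite_df",
]

_MODEL_COLUMNS = {
    1: ("intercept", "period", "beta_a", "beta_b"),
    2: ("intercept", "period", "beta_a", "beta_b", "beta_i"),
    3: ("intercept", "period", "beta_a", "beta_b", "beta_c"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Mean-model choice: 1 additive, 2 interaction, 3 multi-arm."""

    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_COLUMNS:
            raise ValueError(f"unknown model_id {self.model_id}; use 1, 2 or 3")

    @property
    def coef_names(self) -> tuple[str, ...]:
        return _MODEL_COLUMNS[self.model_id]

    @property
    def n_params(self) -> int:
        return len(self.coef_names)


def design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-effect matrix, response and participant labels.

    Rows are grouped by participant and ordered by period; columns follow
    ``spec.coef_names``.
    """
    data = data.sort_values(["participant", "period"], kind="stable")
    j = data["period"].to_numpy(dtype=float)
    one = np.ones_like(j)
    if spec.model_id == 1:
        cols = [one, j, data["x_a"].to_numpy(float), data["x_b"].to_numpy(float)]
    elif spec.model_id == 2:
        xa = data["x_a"].to_numpy(float)
        xb = data["x_b"].to_numpy(float)
        cols = [one, j, xa, xb, xa * xb]
    else:
        cols = [
            one,
            j,
            data["z_a"].to_numpy(float),
            data["z_b"].to_numpy(float),
            data["z_c"].to_numpy(float),
        ]
    X = np.column_stack(cols)
    y = data["y"].to_numpy(dtype=float)
    groups = data["participant"].to_numpy()
    return X, y, groups


@dataclass
class FitResult:
    """Coefficients, covariances and test metadata from one model fit."""

    estimator: str  # "LMM", "GEE" or "GEE-MD"
    coef_names: tuple[str, ...]
    coef: np.ndarray
    vcov: np.ndarray  # primary vcov for this estimator tag
    df: np.ndarray  # per-coefficient degrees of freedom
    converged: bool
    n_iter: int
    n_clusters: int
    n_obs: int
    tau2: float | None = None
    sigma2: float | None = None
    loglik: float | None = None
    vcov_model: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None
    vcov_md: np.ndarray | None = None
    alpha_work: float | None = None
    scale: float | None = None
    df_fallback: bool = False
    extra: dict = field(default_factory=dict)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def tvalues(self) -> np.ndarray:
        return self.coef / self.se()

    def pvalues(self) -> np.ndarray:
        return 2 * stats.t.sf(np.abs(self.tvalues()), self.df)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se(),
                "df": self.df,
                "t": self.tvalues(),
                "p": self.pvalues(),
            },
            index=list(self.coef_names),
        )

    def to_json(self) -> str:
        payload = {
            "estimator": self.estimator,
            "coef_names": list(self.coef_names),
            "coef": self.coef.tolist(),
            "se": self.se().tolist(),
            "df": np.asarray(self.df, dtype=float).tolist(),
            "p": self.pvalues().tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_clusters": int(self.n_clusters),
            "n_obs": int(self.n_obs),
        }
        for name in ("tau2", "sigma2", "loglik", "alpha_work", "scale"):
            value = getattr(self, name)
            if value is not None:
                payload[name] = float(value)
        if self.df_fallback:
            payload["df_fallback"] = True
        return json.dumps(payload)


# ---------------------------------------------------------------------------
# clustered sufficient statistics
# ---------------------------------------------------------------------------


class _ClusterStats:
    """Sufficient statistics for compound-symmetry GLS.

    For every participant only the within-cluster column sums of X and y are
    needed besides the pooled cross-products, because the inverse of
    ``I + lam 11'`` is ``I - lam/(1+n lam) 11'``.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order_ok = True
        change = np.flatnonzero(groups[1:] != groups[:-1])
        starts = np.r_[0, change + 1]
        # groups must be contiguous blocks
        if len(np.unique(groups)) != len(starts):
            order_ok = False
        if not order_ok:
            idx = np.argsort(groups, kind="stable")
            X, y, groups = X[idx], y[idx], groups[idx]
            change = np.flatnonzero(groups[1:] != groups[:-1])
            starts = np.r_[0, change + 1]
        self.X, self.y = X, y
        self.starts = starts
        self.sizes = np.diff(np.r_[starts, len(y)])
        self.n_clusters = len(starts)
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Sx = np.add.reduceat(X, starts, axis=0)  # (m, p) cluster sums
        self.sy = np.add.reduceat(y, starts)  # (m,)

    def rank_check(self) -> None:
        rank = np.linalg.matrix_rank(self.XtX)
        if rank < self.p:
            # identify a minimal set of collinear columns for the message
            _, R = np.linalg.qr(self.X)
            diag = np.abs(np.diag(R))
            bad = [int(i) for i in np.flatnonzero(diag < 1e-8 * diag.max())]
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {self.p}); "
                f"collinear columns: {bad}"
            )

    def gls(self, c: np.ndarray, scale: float = 1.0):
        """GLS pieces for per-cluster weights ``(I - c_i 11') / scale``."""
        A = (self.XtX - (self.Sx * c[:, None]).T @ self.Sx) / scale
        b = (self.Xty - self.Sx.T @ (c * self.sy)) / scale
        q = (self.yty - float(c @ self.sy**2)) / scale
        return A, b, q


def _reml_neg2(lam: float, cs: _ClusterStats) -> tuple[float, dict]:
    """-2 restricted log-likelihood profiled over beta and sigma^2."""
    n, p = cs.n, cs.p
    c = lam / (1.0 + cs.sizes * lam)
    A, b, q = cs.gls(c)
    L = np.linalg.cholesky(A)
    beta = np.linalg.solve(A, b)  # small p: direct solve is fine
    rss = q - float(b @ beta)
    # exact interpolation can cancel to ~0 (or tiny negative) residuals
    rss = max(rss, 1e-290 * max(cs.yty, 1.0))
    sigma2 = rss / (n - p)
    logdet_v0 = float(np.sum(np.log1p(cs.sizes * lam)))
    logdet_a = 2.0 * float(np.sum(np.log(np.diag(L))))
    crit = (
        (n - p) * (np.log(sigma2) + 1.0 + np.log(2 * np.pi))
        + logdet_v0
        + logdet_a
    )
    return crit, {"beta": beta, "sigma2": sigma2, "A": A}


def _reml_loglik_theta(tau2: float, sigma2: float, cs: _ClusterStats) -> float:
    """Restricted log-likelihood at fixed variance components."""
    n, p = cs.n, cs.p
    c = tau2 / (sigma2 + cs.sizes * tau2)
    A, b, q = cs.gls(c, scale=sigma2)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(A, b)
    quad = q - float(b @ beta)
    logdet_v = float(
        np.sum((cs.sizes - 1) * np.log(sigma2) + np.log(sigma2 + cs.sizes * tau2))
    )
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_a + quad)


def _beta_vcov_theta(tau2: float, sigma2: float, cs: _ClusterStats) -> np.ndarray:
    c = tau2 / (sigma2 + cs.sizes * tau2)
    A, _, _ = cs.gls(c, scale=sigma2)
    return np.linalg.inv(A)


class RandomInterceptLMM(BaseEstimator):
    """REML linear mixed model with a participant random intercept.

    scikit-learn style estimator: ``fit(X, y, groups)`` with a fixed-effect
    matrix ``X`` (including the intercept column), response ``y`` and
    cluster labels ``groups``.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        GLS fixed-effect estimates at the REML variance components.
    tau2_, sigma2_ : float
        Random-intercept and residual variance estimates; ``tau2_`` may be 0
        (boundary REML).
    vcov_ : ndarray of shape (p, p)
        Model-based covariance of ``coef_``.
    loglik_ : float
        Restricted log-likelihood at the optimum.
    """

    def __init__(self, tol: float = 1e-10, max_log_ratio: float = 25.0):
        self.tol = tol
        self.max_log_ratio = max_log_ratio

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(y) != len(X) or len(groups) != len(X):
            raise ValueError("X, y and groups must have matching first dimension")
        cs = _ClusterStats(X, y, groups)
        if cs.n_clusters < 2:
            raise ValueError("at least two participants are required")
        cs.rank_check()

        res = optimize.minimize_scalar(
            lambda t: _reml_neg2(np.exp(t), cs)[0],
            bounds=(-self.max_log_ratio, self.max_log_ratio),
            method="bounded",
            options={"xatol": self.tol},
        )
        crit_in, lam = res.fun, float(np.exp(res.x))
        crit_0, _ = _reml_neg2(0.0, cs)
        if crit_0 <= crit_in:  # boundary solution tau^2 = 0
            lam = 0.0
        crit, aux = _reml_neg2(lam, cs)
        sigma2 = aux["sigma2"]
        tau2 = lam * sigma2
        self.coef_ = aux["beta"]
        self.tau2_ = float(tau2)
        self.sigma2_ = float(sigma2)
        self.vcov_ = _beta_vcov_theta(tau2, sigma2, cs)
        self.loglik_ = _reml_loglik_theta(max(tau2, 0.0), sigma2, cs)
        self.converged_ = bool(res.success or lam == 0.0)
        self.n_iter_ = int(res.nfev)
        self.n_clusters_ = cs.n_clusters
        self.n_obs_ = cs.n
        self._cluster_stats = cs
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_

    # -- inference -------------------------------------------------------

    def _information(self) -> np.ndarray | None:
        """Observed REML information of (tau^2, sigma^2), finite differences."""
        cs = self._cluster_stats
        th = np.array([self.tau2_, self.sigma2_])
        h = 1e-4 * np.maximum(np.abs(th), 1e-4)
        H = np.empty((2, 2))
        f0 = _reml_loglik_theta(th[0], th[1], cs)

        def f(a, b):
            if a < 0 or b <= 0:
                return -np.inf
            return _reml_loglik_theta(a, b, cs)

        for i in range(2):
            for k in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ek = np.eye(2)[k] * h[k]
                if i == k:
                    val = (f(*(th + ei)) - 2 * f0 + f(*(th - ei))) / h[i] ** 2
                else:
                    val = (
                        f(*(th + ei + ek))
                        - f(*(th + ei - ek))
                        - f(*(th - ei + ek))
                        + f(*(th - ei - ek))
                    ) / (4 * h[i] * h[k])
                H[i, k] = H[k, i] = val
        if not np.all(np.isfinite(H)):
            return None
        return -H

    def satterthwaite_df(self, contrast) -> float:
        """Satterthwaite degrees of freedom for a coefficient contrast.

        ``df = 2 (c' V c)^2 / Var(c' V c)`` with the variance obtained by the
        delta method: the gradient of ``c' V(theta) c`` in
        ``theta = (tau^2, sigma^2)`` (central differences, relative step
        1e-5) against the inverse observed REML information. The result is
        clamped to ``[1, n_obs - p]``. At the ``tau^2 = 0`` boundary only
        ``sigma^2`` varies, which recovers the residual df ``n_obs - p``.
        """
        cs = self._cluster_stats
        c = np.asarray(contrast, dtype=float)
        p = cs.p
        df_max = cs.n - p
        fval = float(c @ self.vcov_ @ c)

        if self.tau2_ <= 1e-10 * self.sigma2_:
            # boundary: V = sigma^2 (X'X)^-1, var(sigma2_hat) = 2 sigma^4/(n-p)
            return float(np.clip(df_max, 1, df_max))

        th = np.array([self.tau2_, self.sigma2_])
        h = 1e-5 * np.abs(th)
        grad = np.empty(2)
        for i in range(2):
            e = np.eye(2)[i] * h[i]
            up = c @ _beta_vcov_theta(*(th + e), cs) @ c
            dn = c @ _beta_vcov_theta(*(th - e), cs) @ c
            grad[i] = (up - dn) / (2 * h[i])

        info = self._information()
        fallback = False
        var_f = np.nan
        if info is not None:
            try:
                var_f = float(grad @ np.linalg.solve(info, grad))
            except np.linalg.LinAlgError:
                fallback = True
        else:
            fallback = True
        if fallback or not np.isfinite(var_f) or var_f <= 0:
            warnings.warn(
                "singular REML information; falling back to df = N - p",
                RuntimeWarning,
                stacklevel=2,
            )
            self.df_fallback_ = True
            return float(np.clip(cs.n_clusters - p, 1, df_max))
        df = 2.0 * fval**2 / var_f
        return float(np.clip(df, 1, df_max))


def fit_reml(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one of the mean models by REML; Wald t-tests use Satterthwaite df."""
    X, y, groups = design_matrix(data, spec)
    est = RandomInterceptLMM().fit(X, y, groups)
    p = spec.n_params
    df = np.array(
        [est.satterthwaite_df(np.eye(p)[k]) for k in range(p)]
    )
    return FitResult(
        estimator="LMM",
        coef_names=spec.coef_names,
        coef=est.coef_,
        vcov=est.vcov_,
        df=df,
        converged=est.converged_,
        n_iter=est.n_iter_,
        n_clusters=est.n_clusters_,
        n_obs=est.n_obs_,
        tau2=est.tau2_,
        sigma2=est.sigma2_,
        loglik=est.loglik_,
        vcov_model=est.vcov_,
        df_fallback=getattr(est, "df_fallback_", False),
        extra={"_estimator": est},
    )


def satterthwaite_df(fit: FitResult, contrast) -> float:
    """Satterthwaite df for a contrast of a fitted LMM ``FitResult``."""
    est = fit.extra.get("_estimator")
    if est is None:
        raise ValueError(
            "FitResult does not carry its estimator; use "
            "RandomInterceptLMM.satterthwaite_df directly"
        )
    return est.satterthwaite_df(contrast)
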