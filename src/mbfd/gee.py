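"""Generalized estimating equations for MBFD data.

Identity-link Gaussian GEE with an exchangeable working correlation, the
marginal counterpart of the random-intercept mixed model. Coefficients solve
the weighted estimating equations iteratively; the working correlation
``alpha_work`` and scale ``phi`` are moment estimates from Pearson
residuals, updated between coefficient steps.

Inference uses the Liang-Zeger robust (sandwich) covariance and, for small
samples, the Mancl-DeRouen bias-corrected sandwich in which every cluster's
residual vector is pre-multiplied by ``(I - H_i)^{-1}`` (``H_i`` the cluster
leverage) before forming the meat. Wald t-tests use ``df = N - p`` with N
the number of participants.

Moment-estimator conventions (fixed so results are reproducible): the scale
uses denominator ``sum(n_i) - p``; the correlation pools all within-cluster
pairs with denominator ``(number of pairs) - p``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .lmm import FitResult, ModelSpec, _ClusterStats, design_matrix

__all__ = ["ExchangeableGEE", "fit_gee", "md_variance", "gee_test"]


class ExchangeableGEE(BaseEstimator):
    """Gaussian GEE with exchangeable working correlation.

    Parameters
    ----------
    working_corr : float or None
        ``None`` (default) estimates the exchangeable correlation by
        moments. A fixed value bypasses estimation — 0.0 makes the fit
        ordinary least squares; the true correlation makes it closed-form
        GLS (both used as test oracles).
    tol : float
        Convergence threshold on the max absolute coefficient change.
    max_iter : int
        Estimating-equation iteration cap; non-convergence is flagged via
        ``converged_``, never silent.

    Attributes
    ----------
    coef_, vcov_model_, vcov_robust_, vcov_md_ : fitted coefficients and the
        model-based, sandwich and Mancl-DeRouen covariance estimates.
    alpha_work_, scale_ : working-correlation and scale moment estimates.
    """

    def __init__(
        self,
        working_corr: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 50,
    ):
        self.working_corr = working_corr
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        cs = _ClusterStats(X, y, groups)
        if cs.n_clusters <= cs.p:
            raise ValueError(
                f"need more than p={cs.p} participants, got {cs.n_clusters}"
            )
        cs.rank_check()
        n, p = cs.n, cs.p
        sizes = cs.sizes
        npairs = float(np.sum(sizes * (sizes - 1)) / 2)
        alpha_max = 1.0 - 1e-8
        alpha_min = -1.0 / (sizes.max() - 1) + 1e-8 if sizes.max() > 1 else 0.0

        beta = np.linalg.solve(cs.XtX, cs.Xty)  # OLS start
        alpha = 0.0 if self.working_corr is None else float(self.working_corr)
        phi = np.nan
        converged = False
        clipped = False
        for it in range(1, self.max_iter + 1):
            resid = y - X @ beta
            se_cluster = np.add.reduceat(resid, cs.starts)
            phi = float(resid @ resid) / (n - p)
            if self.working_corr is None:
                cross = float(se_cluster @ se_cluster - resid @ resid) / 2.0
                alpha = cross / (phi * (npairs - p))
                if not alpha_min < alpha < alpha_max:
                    alpha = float(np.clip(alpha, alpha_min, alpha_max))
                    clipped = True
            # V0^-1 = (I - c 11')/(1-alpha), c = alpha/(1-alpha+n_i alpha)
            c = alpha / (1.0 - alpha + sizes * alpha)
            A, b, _ = cs.gls(c, scale=1.0 - alpha)
            beta_new = np.linalg.solve(A, b)
            if np.max(np.abs(beta_new - beta)) < self.tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        if clipped:
            warnings.warn(
                "working correlation estimate clipped to its admissible range",
                RuntimeWarning,
                stacklevel=2,
            )
        if not converged:
            warnings.warn(
                f"GEE did not converge in {self.max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )

        resid = y - X @ beta
        se_cluster = np.add.reduceat(resid, cs.starts)
        c = alpha / (1.0 - alpha + sizes * alpha)
        A, _, _ = cs.gls(c, scale=1.0 - alpha)
        A_inv = np.linalg.inv(A)

        # sandwich meat: u_i = X_i' V0_i^-1 e_i (phi cancels in B^-1 M B^-1)
        Xe = np.add.reduceat(X * resid[:, None], cs.starts, axis=0)
        U = (Xe - cs.Sx * (c * se_cluster)[:, None]) / (1.0 - alpha)
        meat = U.T @ U

        # Mancl-DeRouen: inflate each cluster residual by (I - H_i)^-1
        U_md = np.empty_like(U)
        for i, (s0, ni) in enumerate(zip(cs.starts, sizes)):
            Xi = X[s0 : s0 + ni]
            ei = resid[s0 : s0 + ni]
            V0inv = (np.eye(ni) - c[i] * np.ones((ni, ni))) / (1.0 - alpha)
            Hi = Xi @ A_inv @ Xi.T @ V0inv
            try:
                e_adj = np.linalg.solve(np.eye(ni) - Hi, ei)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"(I - H) is singular for cluster {i}"
                ) from exc
            U_md[i] = Xi.T @ V0inv @ e_adj
        meat_md = U_md.T @ U_md

        self.coef_ = beta
        self.alpha_work_ = float(alpha)
        self.scale_ = float(phi)
        self.vcov_model_ = phi * A_inv
        self.vcov_robust_ = A_inv @ meat @ A_inv
        self.vcov_md_ = A_inv @ meat_md @ A_inv
        self.converged_ = converged
        self.n_iter_ = it
        self.n_clusters_ = cs.n_clusters
        self.n_obs_ = n
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


def fit_gee(
    data: pd.DataFrame, spec: ModelSpec, working_corr: float | None = None
) -> FitResult:
    """Fit a mean model by exchangeable GEE.

    The returned ``FitResult`` carries the robust covariance as primary
    ``vcov`` (estimator tag "GEE") plus the model-based and Mancl-DeRouen
    covariances; tests use ``df = N - p``.
    """
    X, y, groups = design_matrix(data, spec)
    est = ExchangeableGEE(working_corr=working_corr).fit(X, y, groups)
    p = spec.n_params
    df = np.full(p, float(est.n_clusters_ - p))
    return FitResult(
        estimator="GEE",
        coef_names=spec.coef_names,
        coef=est.coef_,
        vcov=est.vcov_robust_,
        df=df,
        converged=est.converged_,
        n_iter=est.n_iter_,
        n_clusters=est.n_clusters_,
        n_obs=est.n_obs_,
        vcov_model=est.vcov_model_,
        vcov_robust=est.vcov_robust_,
        vcov_md=est.vcov_md_,
        alpha_work=est.alpha_work_,
        scale=est.scale_,
        extra={"_estimator": est},
    )


def md_variance(fit: FitResult) -> np.ndarray:
    """Mancl-DeRouen bias-corrected sandwich covariance of a GEE fit."""
    if fit.vcov_md is None:
        raise ValueError("fit does not carry a Mancl-DeRouen covariance")
    if not fit.converged:
        raise ValueError("Mancl-DeRouen correction requires a converged fit")
    return fit.vcov_md


def gee_test(
    fit: FitResult,
    contrast,
    variance_kind: str = "robust",
    df: float | None = None,
) -> tuple[float, float, float]:
    """Two-sided Wald t-test of a coefficient contrast.

    Returns ``(t, df, p)`` with the requested variance ("robust" or "md").
    The default reference is t with ``df = N - p``; pass ``df=numpy.inf``
    for the large-sample normal reference that GEE software reports by
    default.
    """
    c = np.asarray(contrast, dtype=float)
    vcov = {"robust": fit.vcov_robust, "md": fit.vcov_md}.get(variance_kind)
    if vcov is None:
        raise ValueError(f"unknown variance_kind {variance_kind!r}")
    if df is None:
        df = fit.n_clusters - len(fit.coef)
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    est = float(c @ fit.coef)
    se = float(np.sqrt(c @ vcov @ c))
    t = est / se
    p = float(2 * stats.t.sf(abs(t), df))
    return t, float(df), p
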