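"""Random-intercept linear mixed model fitted by profiled likelihood.

The model is

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with one random intercept per group (here: per sequencing library).
Because there is a single variance ratio theta = tau^2 / sigma^2, both
beta and sigma^2 can be profiled out in closed form and the (restricted)
log-likelihood reduces to a one-dimensional function of theta, which is
maximized by bounded scalar optimization. Each evaluation costs
O(n + G p^2) using per-group sufficient statistics, making thousands of
per-gene fits cheap.

For a group j with n_j rows, V_j = I + theta * 1 1' and
V_j^{-1} = I - c_j J with c_j = theta / (1 + n_j theta), which is all
that is needed for the GLS normal equations and the quadratic form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["LMMFit", "fit_random_intercept"]

_LOG_THETA_BOUNDS = (-15.0, 15.0)
_BOUNDARY_LOG_THETA = -30.0  # numerically theta = 0: pure fixed-effects model


@dataclass
class LMMFit:
    """Result of a random-intercept fit.

    Attributes
    ----------
    beta : estimated fixed-effect coefficients.
    se : standard errors of ``beta`` (model-based GLS covariance).
    tau2 : between-group (library) variance component.
    sigma2 : residual variance component.
    n_groups : number of groups (libraries).
    boundary : True when tau2 was estimated at the zero boundary, in
        which case the fit coincides with ordinary least squares.
    """

    beta: np.ndarray
    se: np.ndarray
    tau2: float
    sigma2: float
    n_obs: int
    n_groups: int
    reml: bool
    boundary: bool
    df_satterthwaite: np.ndarray | None = None


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, starts = np.unique(gs, return_index=True)
    bounds = np.append(starts, len(gs))
    out = []
    for i in range(len(starts)):
        sl = slice(bounds[i], bounds[i + 1])
        Xg, yg = Xs[sl], ys[sl]
        out.append((Xg.T @ Xg, Xg.T @ yg, Xg.sum(axis=0), yg.sum(), yg @ yg, Xg, yg, sl.stop - sl.start))
    return out


def _vc_quantities(tau2: float, sigma2: float, pre, N: int, p: int, reml: bool):
    """Criterion (-2 x log-likelihood up to constants) and GLS pieces at
    explicit variance components (tau2, sigma2)."""
    M = np.zeros((p, p))
    Mty = np.zeros(p)
    for GtG, Gty, xs, ys, yy, Xg, yg, n in pre:
        c = tau2 / (sigma2 + n * tau2)
        M += GtG - c * np.outer(xs, xs)
        Mty += Gty - c * xs * ys
    beta = np.linalg.solve(M, Mty)
    rss = 0.0
    logdet_v = 0.0
    for GtG, Gty, xs, ys, yy, Xg, yg, n in pre:
        c = tau2 / (sigma2 + n * tau2)
        rss += yy - 2 * beta @ Gty + beta @ GtG @ beta - c * (ys - xs @ beta) ** 2
        logdet_v += (n - 1) * np.log(sigma2) + np.log(sigma2 + n * tau2)
    crit = logdet_v + rss / sigma2
    if reml:
        # |X' V^-1 X| = |M| / sigma2^p
        crit += np.linalg.slogdet(M)[1] - p * np.log(sigma2)
    cov_beta = sigma2 * np.linalg.inv(M)
    return crit, cov_beta


def _satterthwaite_df(tau2: float, sigma2: float, pre, N: int, p: int, reml: bool) -> np.ndarray:
    """Per-coefficient Satterthwaite df: 2 f^2 / Var(f), f = Var(beta_k).

    Var(f) comes from the delta method, with the variance-component
    covariance taken as the inverse observed information of the
    (restricted) likelihood; both the information and the gradient of f
    are evaluated by central finite differences.
    """
    x0 = np.array([tau2, sigma2])
    h = np.maximum(1e-4 * x0, 1e-10)

    def crit(v):
        return _vc_quantities(max(v[0], 0.0), max(v[1], 1e-300), pre, N, p, reml)[0]

    def var_beta(v):
        return np.diag(_vc_quantities(max(v[0], 0.0), max(v[1], 1e-300), pre, N, p, reml)[1])

    e = np.eye(2)
    H = np.empty((2, 2))
    f0 = crit(x0)
    for i in range(2):
        H[i, i] = (crit(x0 + h[i] * e[i]) - 2 * f0 + crit(x0 - h[i] * e[i])) / h[i] ** 2
    H[0, 1] = H[1, 0] = (
        crit(x0 + h[0] * e[0] + h[1] * e[1])
        - crit(x0 + h[0] * e[0] - h[1] * e[1])
        - crit(x0 - h[0] * e[0] + h[1] * e[1])
        + crit(x0 - h[0] * e[0] - h[1] * e[1])
    ) / (4 * h[0] * h[1])
    # crit is -2*loglik: information = H/2, vcov of components = 2*H^-1
    A = 2.0 * np.linalg.inv(H)
    grad = np.empty((2, p))
    for i in range(2):
        grad[i] = (var_beta(x0 + h[i] * e[i]) - var_beta(x0 - h[i] * e[i])) / (2 * h[i])
    f = var_beta(x0)
    denom = np.einsum("ik,ij,jk->k", grad, A, grad)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * f**2 / denom
    df = np.where((denom <= 0) | ~np.isfinite(df), N - p, df)
    return np.clip(df, 1.0, N - p)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
    compute_df: bool = False,
) -> LMMFit:
    """Fit the random-intercept model, profiling the variance ratio.

    Parameters
    ----------
    y
        Response vector, length n.
    X
        Fixed-effects design matrix, shape (n, p), including the
        intercept column.
    groups
        Group label per row (any hashable dtype).
    reml
        Maximize the restricted likelihood (default). REML corrects the
        downward bias of ML variance estimates, which matters with few
        libraries; set False for plain maximum likelihood.

    Raises
    ------
    ValueError
        On degenerate input (fewer than 2 groups, zero residual
        variance, or rank-deficient design).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    N, p = X.shape
    stats = _group_stats(X, y, groups)
    G = len(stats)
    if G < 2:
        raise ValueError(f"need >= 2 groups for a random-intercept fit, got {G}")
    if N <= p:
        raise ValueError(f"need more observations ({N}) than fixed parameters ({p})")

    denom = N - p if reml else N

    def profile(log_theta: float):
        th = np.exp(log_theta)
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        for GtG, Gty, xs, ys, yy, Xg, yg, n in stats:
            c = th / (1.0 + n * th)
            XtX += GtG - c * np.outer(xs, xs)
            Xty += Gty - c * xs * ys
        try:
            beta = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError as exc:
            raise ValueError("rank-deficient fixed-effects design") from exc
        rss = 0.0
        logdet_v = 0.0
        for GtG, Gty, xs, ys, yy, Xg, yg, n in stats:
            c = th / (1.0 + n * th)
            r_sum = ys - xs @ beta
            rss += yy - 2 * beta @ Gty + beta @ GtG @ beta - c * r_sum**2
            logdet_v += np.log1p(n * th)
        rss = max(rss, 0.0)
        if rss == 0.0:
            raise ValueError("zero residual variance: response is exactly collinear with the design")
        s2 = rss / denom
        crit = denom * np.log(s2) + logdet_v
        if reml:
            sign, logdet_x = np.linalg.slogdet(XtX)
            crit += logdet_x
        return 0.5 * crit, beta, s2, XtX

    res = optimize.minimize_scalar(
        lambda lt: profile(lt)[0], bounds=_LOG_THETA_BOUNDS, method="bounded"
    )
    # the profiled criterion can be monotone decreasing toward theta=0;
    # compare the interior optimum against the boundary explicitly
    best = res.x
    if profile(_BOUNDARY_LOG_THETA)[0] <= profile(best)[0]:
        best = _BOUNDARY_LOG_THETA
    crit, beta, s2, XtX = profile(best)
    boundary = best == _BOUNDARY_LOG_THETA
    theta = 0.0 if boundary else float(np.exp(best))
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    df_sat = None
    if compute_df:
        if boundary:
            # no library variance: the fit is OLS and carries residual df
            df_sat = np.full(p, float(N - p))
        else:
            try:
                df_sat = _satterthwaite_df(theta * s2, s2, stats, N, p, reml)
            except np.linalg.LinAlgError:
                df_sat = np.full(p, float(max(G - p, 1)))
    return LMMFit(
        beta=beta,
        se=se,
        tau2=theta * s2,
        sigma2=float(s2),
        n_obs=N,
        n_groups=G,
        reml=reml,
        boundary=boundary,
        df_satterthwaite=df_sat,
    )
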