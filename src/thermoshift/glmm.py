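"""Poisson generalized linear mixed model with a random intercept.

    y_ij ~ Poisson(exp(x_ij' beta + b_i)),   b_i ~ N(0, tau^2)

fitted by maximum likelihood with adaptive Gauss–Hermite quadrature.  The
group-level integral depends on the data only through the group sums of
``y`` and of ``exp(x'beta)``, so each likelihood evaluation vectorises over
groups: per group the integrand mode is found by a damped Newton iteration
and the quadrature grid is centred and scaled there.  Wald z-tests are
reported for the coefficients (the usual convention for ML-fitted GLMMs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

_LOG_TAU_MIN, _LOG_TAU_MAX = -8.0, 3.0


def _group_laplace_mode(s_y, s_e, tau2, n_iter: int = 50):
    """Mode of b -> b*s_y - exp(b)*s_e - b^2/(2 tau^2), vectorised."""
    b = np.log(np.maximum(s_y, 0.5) / s_e)  # starting point: group MLE
    for _ in range(n_iter):
        eb = np.exp(b)
        grad = s_y - eb * s_e - b / tau2
        hess = -eb * s_e - 1.0 / tau2
        step = grad / hess
        step = np.clip(step, -2.0, 2.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-12:
            break
    return b


class PoissonGLMM(BaseEstimator):
    """Random-intercept Poisson GLMM (log link), adaptive GH quadrature.

    Parameters
    ----------
    n_quad : int
        Gauss–Hermite nodes (default 15; the integrand is close to
        Gaussian after adaptation, so modest orders suffice).

    Attributes
    ----------
    coef_, bse_, zvalues_, pvalues_ : pandas.Series
        Fixed effects on the log scale with Wald z inference.
    tau_ : float
        Random-intercept SD.
    loglik_ : float
    converged_ : bool
    """

    def __init__(self, n_quad: int = 15):
        self.n_quad = n_quad

    def fit(self, X, y, groups):
        X = pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("counts must be non-negative integers")
        groups = np.asarray(groups)
        n, p = Xm.shape
        codes, _ = pd.factorize(groups, sort=True)
        order = np.argsort(codes, kind="stable")
        Xs, ys, cs = Xm[order], y[order], codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(cs) > 0])
        G = starts.size
        s_y = np.add.reduceat(ys, starts)
        log_yfact = float(special.gammaln(ys + 1.0).sum())
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
        logw = np.log(weights)

        def negll(params):
            beta, log_tau = params[:p], params[p]
            log_tau = np.clip(log_tau, _LOG_TAU_MIN, _LOG_TAU_MAX)
            tau2 = np.exp(2.0 * log_tau)
            eta = Xs @ beta
            if np.max(np.abs(eta)) > 200:
                return np.inf
            s_e = np.add.reduceat(np.exp(eta), starts)
            s_ye = np.add.reduceat(ys * eta, starts)
            bhat = _group_laplace_mode(s_y, s_e, tau2)
            sig = 1.0 / np.sqrt(np.exp(bhat) * s_e + 1.0 / tau2)
            # b grid: (G, K)
            b = bhat[:, None] + np.sqrt(2.0) * sig[:, None] * nodes[None, :]
            logf = (
                b * s_y[:, None]
                - np.exp(b) * s_e[:, None]
                - b**2 / (2.0 * tau2)
                - 0.5 * np.log(2.0 * np.pi * tau2)
            )
            # adaptive GH: integral = sqrt(2)*sig * sum_k w_k exp(x_k^2) f(b_k)
            log_int = special.logsumexp(
                logf + logw[None, :] + nodes[None, :] ** 2, axis=1
            ) + 0.5 * np.log(2.0) + np.log(sig)
            ll = float(s_ye.sum() + log_int.sum()) - log_yfact
            return -ll if np.isfinite(ll) else np.inf

        # start from the marginal Poisson GLM (IRLS)
        beta0 = np.zeros(p)
        for _ in range(50):
            mu = np.exp(np.clip(Xs @ beta0, -30, 30))
            W = mu
            z = Xs @ beta0 + (ys - mu) / np.maximum(mu, 1e-8)
            XtW = Xs.T * W
            try:
                beta_new = np.linalg.solve(XtW @ Xs, XtW @ z)
            except np.linalg.LinAlgError:
                break
            if np.max(np.abs(beta_new - beta0)) < 1e-10:
                beta0 = beta_new
                break
            beta0 = beta_new
        x0 = np.r_[beta0, np.log(0.5)]

        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 5000, "maxfev": 10000},
        )
        self.converged_ = bool(res.success and np.isfinite(res.fun))
        params = res.x
        self.loglik_ = -float(res.fun)
        self.tau_ = float(np.exp(np.clip(params[p], _LOG_TAU_MIN, _LOG_TAU_MAX)))

        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(params, negll)
        try:
            cov_all = np.linalg.inv(H)
            bse = np.sqrt(np.maximum(np.diag(cov_all)[:p], 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
        self.coef_ = pd.Series(params[:p], index=self.feature_names_)
        self.bse_ = pd.Series(bse, index=self.feature_names_)
        z = self.coef_ / self.bse_
        self.zvalues_ = z
        self.pvalues_ = pd.Series(
            2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=self.feature_names_
        )
        self.n_obs_ = int(n)
        self.n_groups_ = int(G)
        return self

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"lower": self.coef_ - zq * self.bse_, "upper": self.coef_ + zq * self.bse_}
        )
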