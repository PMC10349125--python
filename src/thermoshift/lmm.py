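"""Linear mixed model: random intercept per group, power variance function.

The model for observation j in group (plot) i is

    y_ij = x_ij' beta + b_i + e_ij,
    b_i ~ N(0, tau^2),   e_ij ~ N(0, sigma^2 * |v_ij|^(2 delta)),

where ``v`` is a positive variance covariate and ``delta`` the estimated
power-variance exponent (``delta = 0`` recovers the homoscedastic
random-intercept LMM).  This mirrors an ``lme(..., random = ~1 | group,
weights = varPower(form = ~v))`` fit; residual variance typically
*decreases* with the number of species behind a community statistic, giving
``delta < 0``.

Estimation is (RE)ML with ``beta`` and ``sigma^2`` profiled out and the
variance parameters ``(log gamma, delta)`` (``gamma = tau^2 / sigma^2``)
optimised numerically.  Group-wise covariance inverses use the rank-one
Woodbury identity, so each likelihood evaluation is linear in the number of
observations.

Inference: Wald t-tests with between–within denominator degrees of freedom
(an approximation: within-group-varying covariates use ``n_obs - n_groups -
p_within``, purely between-group covariates ``n_groups - p_between - 1``),
and marginal (type-III style) Wald F-tests per term.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -23.0, 14.0
_DELTA_MIN, _DELTA_MAX = -5.0, 5.0


class PowerVarianceLMM(BaseEstimator):
    """Random-intercept linear mixed model with optional power variance.

    Parameters
    ----------
    estimate_power : bool
        Estimate the power-variance exponent delta.  Requires a variance
        covariate at fit time; with ``False`` the residual is homoscedastic.
    reml : bool
        Restricted maximum likelihood (default) or plain ML.

    Attributes
    ----------
    coef_ : pandas.Series
        Fixed-effect estimates.
    bse_, tvalues_, pvalues_, dof_ : pandas.Series
        Wald standard errors, t statistics, two-sided p values and the
        between–within denominator degrees of freedom per coefficient.
    sigma_, tau_ : float
        Residual scale (at ``v = 1``) and random-intercept SD.
    variance_power_ : float
        Estimated exponent delta (0.0 when not estimated).
    loglik_ : float
        Maximised (restricted) log-likelihood.
    converged_ : bool
    singular_ : bool
        True when the between-group variance collapsed to (near) zero.
    """

    def __init__(self, estimate_power: bool = False, reml: bool = True):
        self.estimate_power = estimate_power
        self.reml = reml

    # ------------------------------------------------------------------
    def fit(self, X, y, groups, variance_covariate=None, theta0=None):
        """Fit the model.

        Parameters
        ----------
        X : DataFrame or 2d array
            Fixed-effects design matrix including the intercept column.
        y : 1d array
        groups : 1d array
            Random-intercept grouping (plot ids).
        variance_covariate : 1d array, optional
            Positive covariate ``v`` of the power variance function;
            required when ``estimate_power=True``.
        theta0 : array, optional
            Warm start for the variance parameters ``(log gamma[, delta])``
            (used by bootstrap refits).
        """
        X = pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        n, p = Xm.shape
        if n != y.size or n != groups.size:
            raise ValueError("X, y and groups must have matching lengths")
        if self.estimate_power:
            if variance_covariate is None:
                raise ValueError("estimate_power=True requires a variance covariate")
            v = np.asarray(variance_covariate, dtype=float)
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError("variance covariate must be positive and finite")
            logv2 = 2.0 * np.log(v)
        else:
            logv2 = np.zeros(n)

        codes, uniques = pd.factorize(groups, sort=True)
        order = np.argsort(codes, kind="stable")
        Xs, ys, cs, lv2 = Xm[order], y[order], codes[order], logv2[order]
        starts = np.flatnonzero(np.r_[True, np.diff(cs) > 0])
        G = starts.size
        if np.linalg.matrix_rank(Xm) < p:
            raise np.linalg.LinAlgError("fixed-effects design matrix is rank deficient")

        def profile(theta):
            """Profiled deviance pieces for theta = (log gamma[, delta])."""
            log_gamma = theta[0]
            delta = theta[1] if self.estimate_power else 0.0
            gamma = np.exp(log_gamma)
            logw = delta * lv2
            u = np.exp(-logw)  # 1 / w
            s = np.add.reduceat(u, starts)
            c = gamma / (1.0 + gamma * s)
            Xu = Xs * u[:, None]
            Xu1 = np.add.reduceat(Xu, starts, axis=0)  # (G, p)
            yu1 = np.add.reduceat(ys * u, starts)
            XtAX = Xu.T @ Xs - (Xu1 * c[:, None]).T @ Xu1
            XtAy = Xu.T @ ys - Xu1.T @ (c * yu1)
            beta = np.linalg.solve(XtAX, XtAy)
            r = ys - Xs @ beta
            ru = r * u
            ru1 = np.add.reduceat(ru, starts)
            q = float(ru @ r - c @ ru1**2)
            logdetA = float(logw.sum() + np.log1p(gamma * s).sum())
            return beta, XtAX, q, logdetA

        def neg2ll(theta):
            try:
                _, XtAX, q, logdetA = profile(theta)
            except np.linalg.LinAlgError:
                return np.inf
            if not np.isfinite(q) or q <= 0:
                return np.inf
            if self.reml:
                dof = n - p
                sign, logdetX = np.linalg.slogdet(XtAX)
                if sign <= 0:
                    return np.inf
                return (
                    dof * (np.log(2.0 * np.pi * q / dof) + 1.0) + logdetA + logdetX
                )
            return n * (np.log(2.0 * np.pi * q / n) + 1.0) + logdetA

        if theta0 is not None:
            x0s = [np.asarray(theta0, dtype=float)]
        elif self.estimate_power:
            x0s = [np.array([-1.0, 0.0]), np.array([-4.0, -1.0]), np.array([1.0, 0.0])]
        else:
            x0s = [np.array([-1.0]), np.array([-6.0]), np.array([2.0])]
        bounds = [(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] + (
            [(_DELTA_MIN, _DELTA_MAX)] if self.estimate_power else []
        )
        best = None
        for x0 in x0s:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    neg2ll, x0, method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
                )
            res.x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            res.fun = neg2ll(res.x)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        theta = best.x
        self.theta_ = np.array(theta, dtype=float)
        self.converged_ = bool(np.isfinite(best.fun))

        beta, XtAX, q, _ = profile(theta)
        dof = (n - p) if self.reml else n
        sigma2 = q / dof
        gamma = float(np.exp(theta[0]))
        self.variance_power_ = float(theta[1]) if self.estimate_power else 0.0
        self.sigma_ = float(np.sqrt(sigma2))
        self.tau_ = float(np.sqrt(sigma2 * gamma))
        self.singular_ = theta[0] <= _LOG_GAMMA_MIN + 1e-6
        self.loglik_ = -0.5 * float(best.fun)
        cov = sigma2 * np.linalg.inv(XtAX)
        self.cov_params_ = pd.DataFrame(
            cov, index=self.feature_names_, columns=self.feature_names_
        )
        self.coef_ = pd.Series(beta, index=self.feature_names_)
        self.bse_ = pd.Series(np.sqrt(np.diag(cov)), index=self.feature_names_)

        # between-within denominator degrees of freedom
        within = np.zeros(p, dtype=bool)
        for j in range(p):
            col = Xs[:, j]
            gmean = np.add.reduceat(col, starts) / np.add.reduceat(
                np.ones_like(col), starts
            )
            within[j] = np.any(np.abs(col - np.repeat(gmean, np.diff(np.r_[starts, n]))) > 1e-10)
        p_within = int(within.sum())
        p_between = p - p_within
        ddf_within = max(n - G - p_within, 1)
        ddf_between = max(G - p_between, 1)
        ddf = np.where(within, ddf_within, ddf_between).astype(float)
        self.dof_ = pd.Series(ddf, index=self.feature_names_)
        tvals = beta / self.bse_.to_numpy()
        self.tvalues_ = pd.Series(tvals, index=self.feature_names_)
        self.pvalues_ = pd.Series(
            2.0 * stats.t.sf(np.abs(tvals), ddf), index=self.feature_names_
        )
        self.n_obs_ = int(n)
        self.n_groups_ = int(G)
        self._within_mask_ = within
        if self.singular_:
            log.warning(
                "between-group variance collapsed to ~0 (singular fit); "
                "estimates equal the marginal (GLS) regression"
            )
        return self

    # ------------------------------------------------------------------
    def wald_f_test(self, columns: list[str]) -> tuple[float, int, float, float]:
        """Marginal Wald F-test that the named coefficients are jointly zero.

        Returns ``(F, df_num, df_den, p)``; df_den is the smallest
        between–within ddf among the tested columns.
        """
        idx = [self.feature_names_.index(c) for c in columns]
        b = self.coef_.to_numpy()[idx]
        V = self.cov_params_.to_numpy()[np.ix_(idx, idx)]
        fstat = float(b @ np.linalg.solve(V, b)) / len(idx)
        ddf = float(self.dof_.iloc[idx].min())
        pval = float(stats.f.sf(fstat, len(idx), ddf))
        return fstat, len(idx), ddf, pval

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald confidence intervals with between–within ddf."""
        tq = stats.t.ppf(0.5 + level / 2.0, self.dof_.to_numpy())
        return pd.DataFrame(
            {
                "lower": self.coef_ - tq * self.bse_,
                "upper": self.coef_ + tq * self.bse_,
            }
        )
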