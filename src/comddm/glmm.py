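"""Random-intercept logistic regression fit by maximum likelihood.

Implements the mixed-effects logistic model
    logit P(y_ij = 1) = x_ij' beta + b_j,   b_j ~ N(0, sigma^2),
with the marginal likelihood integrated over b_j by adaptive Gauss-Hermite
quadrature (mode + curvature recentering per group; nAGQ = 1 reduces to the
Laplace approximation, the lme4 default).  Only a random intercept is
supported, which is all the behavioural analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

__all__ = ["LogisticGLMM", "GLMMResult", "lr_test"]


@dataclass
class GLMMResult:
    """ML estimates for a random-intercept logistic GLMM."""

    params: np.ndarray  # fixed effects
    sigma: float  # random-intercept SD
    loglike: float
    names: list[str]
    converged: bool
    n_obs: int
    n_groups: int

    @property
    def aic(self) -> float:
        k = len(self.params) + 1
        return 2 * k - 2 * self.loglike

    def coef(self) -> pd.Series:
        return pd.Series(self.params, index=self.names)

    def pseudo_r2(self, X: np.ndarray) -> dict:
        """Latent-scale marginal/conditional pseudo-R^2 (Nakagawa).

        var_fixed / (var_fixed + sigma^2 + pi^2/3) and the conditional
        analogue with sigma^2 moved to the numerator.
        """
        vf = float(np.var(X @ self.params))
        vr = self.sigma**2
        denom = vf + vr + np.pi**2 / 3
        return {"marginal": vf / denom, "conditional": (vf + vr) / denom}


def _group_loglik(eta_fixed, y, sigma, nodes, weights, newton_iter=30):
    """Adaptive GH marginal log-likelihood of one group.

    Integrand (standardized u ~ N(0,1)):
        h(u) = sum_i [y_i eta_i - log(1 + exp(eta_i))] - u^2/2,
    eta_i = eta_fixed_i + sigma u.  Mode by Newton, then GH about the mode
    scaled by the curvature.
    """
    u = 0.0
    for _ in range(newton_iter):
        eta = eta_fixed + sigma * u
        p = special.expit(eta)
        g = sigma * np.sum(y - p) - u
        h = -(sigma**2) * np.sum(p * (1 - p)) - 1.0
        step = g / h
        u -= step
        if abs(step) < 1e-10:
            break
    eta = eta_fixed + sigma * u
    p = special.expit(eta)
    tau = 1.0 / np.sqrt(sigma**2 * np.sum(p * (1 - p)) + 1.0)
    z = u + np.sqrt(2.0) * tau * nodes  # quadrature abscissae in u-space
    eta_q = eta_fixed[:, None] + sigma * z[None, :]
    # log f(y | u) summed over observations, per node
    ll_obs = y[:, None] * eta_q - np.logaddexp(0.0, eta_q)
    h_q = ll_obs.sum(axis=0) - 0.5 * z**2
    log_terms = np.log(weights) + h_q + nodes**2
    return float(
        special.logsumexp(log_terms) + np.log(tau * np.sqrt(2.0))
        - 0.5 * np.log(2.0 * np.pi)
    )


class LogisticGLMM:
    """ML logistic GLMM with a single random intercept.

    Parameters
    ----------
    formula_terms : list of str
        Column names of ``data`` entering as fixed effects (an intercept is
        always prepended).  Interactions are written "a:b".
    response, group : str
        Response (0/1) and grouping-factor column names.
    nagq : int
        Number of adaptive quadrature nodes (1 = Laplace).
    """

    def __init__(self, data: pd.DataFrame, response: str, terms: list[str],
                 group: str, nagq: int = 10):
        self.data = data
        self.response = response
        self.terms = list(terms)
        self.group = group
        self.nagq = int(nagq)
        self.names = ["Intercept"] + self.terms
        y = data[response].to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        X = [np.ones(len(data))]
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                X.append(data[a].to_numpy(float) * data[b].to_numpy(float))
            else:
                X.append(data[t].to_numpy(float))
        self.X = np.column_stack(X)
        self.y = y
        codes, self._group_levels = pd.factorize(data[group])
        order = np.argsort(codes, kind="stable")
        self._order = order
        self._bounds = np.searchsorted(codes[order], np.arange(len(self._group_levels) + 1))
        self._nodes, self._weights = np.polynomial.hermite.hermgauss(self.nagq)

    def loglike(self, beta: np.ndarray, sigma: float) -> float:
        eta = self.X @ beta
        y, o, b = self.y, self._order, self._bounds
        total = 0.0
        for j in range(len(self._group_levels)):
            idx = o[b[j] : b[j + 1]]
            total += _group_loglik(eta[idx], y[idx], sigma,
                                   self._nodes, self._weights)
        return total

    def fit(self, start: np.ndarray | None = None) -> GLMMResult:
        k = self.X.shape[1]
        if start is None:
            # plain logistic regression start, small positive sigma
            from statsmodels.api import GLM, families

            glm = GLM(self.y, self.X, family=families.Binomial()).fit()
            start = np.append(glm.params, np.log(0.3))

        def nll(theta):
            beta, log_sigma = theta[:-1], theta[-1]
            if log_sigma < -12 or log_sigma > 5:
                return 1e10
            return -self.loglike(beta, np.exp(log_sigma))

        res = optimize.minimize(nll, start, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-6})
        # polish with Nelder-Mead if BFGS stalled on the noisy numeric grad
        if not res.success:
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"maxfev": 4000, "xatol": 1e-8,
                                              "fatol": 1e-9})
            if res2.fun <= res.fun:
                res = res2
        beta, log_sigma = res.x[:-1], res.x[-1]
        return GLMMResult(
            params=beta,
            sigma=float(np.exp(log_sigma)),
            loglike=-float(res.fun),
            names=self.names,
            converged=bool(np.isfinite(res.fun)),
            n_obs=len(self.y),
            n_groups=len(self._group_levels),
        )


def lr_test(ll_full: float, ll_reduced: float, df: int = 1) -> dict:
    """Likelihood-ratio test of nested ML fits."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return {"chi2": stat, "df": df, "p": float(sps.chi2.sf(stat, df))}
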