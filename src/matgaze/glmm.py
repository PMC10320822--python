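"""Logistic mixed models by maximum likelihood with Gauss-Hermite quadrature.

Fits ``y ~ X + (1 | group)`` or ``y ~ X + (1 + z | group)`` for binary
outcomes, with independent normal random effects.  The marginal likelihood
integrates the random effects out with (non-adaptive) Gauss-Hermite
quadrature; fixed-effect Wald statistics come from the observed information
(numerical Hessian of the marginal log-likelihood), and per-group conditional
means of the random effects (posterior means given the data, the analogue of
BLUPs) are computed from the same quadrature at the optimum.

This is the workhorse behind the trial-level accuracy models and the
logistic-link difficulty-adaptation models for the binary strategy indices
(encoding / integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

__all__ = ["GLMMResult", "fit_logistic_mixed"]


@dataclass
class GLMMResult:
    """Fitted logistic mixed model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    re_sd: dict[str, float]
    loglik: float
    converged: bool
    ranef: pd.DataFrame  # per-group posterior means of the random effects
    n_obs: int
    n_groups: int

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        h = norm.ppf(1.0 - alpha / 2.0) * self.se
        return np.column_stack([self.beta - h, self.beta + h])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.names,
                "B": self.beta,
                "se": self.se,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
                "z": self.z,
                "p": self.pvalues,
            }
        )


def _prepare(y, X, groups):
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    codes, uniques = pd.factorize(np.asarray(groups))
    order = np.argsort(codes, kind="stable")
    starts = np.r_[0, np.cumsum(np.bincount(codes))][:-1]
    return y, X, codes, uniques, order, starts


def fit_logistic_mixed(
    y,
    X,
    groups,
    *,
    names: list[str] | None = None,
    slope_of: np.ndarray | None = None,
    n_quad: int = 15,
    start: np.ndarray | None = None,
) -> GLMMResult:
    """ML fit of a logistic random-intercept (and optional random-slope)
    model.

    Parameters
    ----------
    y, X, groups
        Binary outcome, fixed-effect design matrix (include the intercept
        column yourself), and the grouping factor (participants).
    slope_of
        Per-row covariate with a random slope (in addition to the random
        intercept).  ``None`` fits a random intercept only.
    n_quad
        Gauss-Hermite nodes per random-effect dimension (15 is ample for
        the variance magnitudes seen in these models).
    """
    y, X, codes, uniques, order, starts = _prepare(y, X, groups)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    sign = np.where(y > 0.5, 1.0, -1.0)[order]
    Xo = X[order]
    zo = None if slope_of is None else np.asarray(slope_of, float).ravel()[order]
    two_dim = slope_of is not None

    gh_x, gh_w = special.roots_hermite(n_quad)
    u1 = np.sqrt(2.0) * gh_x
    logw1 = np.log(gh_w) - 0.5 * np.log(np.pi)
    if two_dim:
        ui, vj = np.meshgrid(u1, u1, indexing="ij")
        U0, U1 = ui.ravel(), vj.ravel()
        logW = (logw1[:, None] + logw1[None, :]).ravel()
    else:
        U0, U1, logW = u1, None, logw1

    def group_loglik(theta: np.ndarray) -> np.ndarray:
        beta = theta[:p]
        s0 = np.exp(theta[p])
        eta = Xo @ beta
        if two_dim:
            s1 = np.exp(theta[p + 1])
            lin = eta[:, None] + s0 * U0[None, :] + (s1 * zo)[:, None] * U1[None, :]
        else:
            lin = eta[:, None] + s0 * U0[None, :]
        ll_rows = -np.logaddexp(0.0, -sign[:, None] * lin)
        M = np.add.reduceat(ll_rows, starts, axis=0)  # (G, K)
        return special.logsumexp(M + logW[None, :], axis=1)

    def nll(theta: np.ndarray) -> float:
        val = group_loglik(theta).sum()
        return -val if np.isfinite(val) else 1e12

    if start is None:
        p_bar = min(max(y.mean(), 1e-3), 1 - 1e-3)
        start = np.zeros(p + (2 if two_dim else 1))
        col_is_const = np.ptp(X, axis=0) == 0
        if col_is_const.any():
            start[np.argmax(col_is_const)] = np.log(p_bar / (1 - p_bar))
        start[p:] = np.log(0.5)

    res = optimize.minimize(nll, start, method="L-BFGS-B")
    theta = res.x
    converged = bool(res.success)

    # observed information by central differences
    k = theta.size
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        if not np.all(np.isfinite(se)) or np.any(se == 0):
            converged = False
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False

    # posterior means of the random effects per group
    beta = theta[:p]
    s0 = np.exp(theta[p])
    eta = Xo @ beta
    if two_dim:
        s1 = np.exp(theta[p + 1])
        lin = eta[:, None] + s0 * U0[None, :] + (s1 * zo)[:, None] * U1[None, :]
    else:
        lin = eta[:, None] + s0 * U0[None, :]
    ll_rows = -np.logaddexp(0.0, -sign[:, None] * lin)
    M = np.add.reduceat(ll_rows, starts, axis=0) + logW[None, :]
    M -= M.max(axis=1, keepdims=True)
    W = np.exp(M)
    W /= W.sum(axis=1, keepdims=True)
    re0 = s0 * (W @ U0)
    data = {"group": list(uniques), "intercept": re0}
    re_sd = {"intercept": float(s0)}
    if two_dim:
        data["slope"] = s1 * (W @ U1)
        re_sd["slope"] = float(s1)
    ranef = pd.DataFrame(data)

    return GLMMResult(
        names=names,
        beta=beta,
        se=se,
        re_sd=re_sd,
        loglik=float(-f0),
        converged=converged,
        ranef=ranef,
        n_obs=n,
        n_groups=len(uniques),
    )
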