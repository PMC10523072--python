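"""Penalized-spline additive models with random intercepts.

A compact engine for the two seasonal trend models: a single smooth term
(B-spline basis with a difference penalty, from statsmodels' GAM utilities)
plus an optional group random intercept, for Gaussian and binomial
responses.  Random intercepts use the classical mixed-model representation:
a block of group indicator columns under a ridge penalty, whose smoothing
parameter maps to the random-effect variance ``sigma_b^2 = scale /
lambda_group``.

Fitting is penalized IRLS; smoothing parameters are chosen by minimizing
GCV (Gaussian) or UBRE (binomial, scale fixed at 1) over log-lambdas with
Nelder-Mead.  Effective degrees of freedom are traces of the influence
matrix, reported per block.  The smooth term's significance is a Wald test
on its coefficient block with rank-truncated covariance (degrees of freedom
= rounded block edf), in the spirit of the approximate smooth tests used by
mixed-GAM software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.gam.smooth_basis import BSplines

__all__ = ["PenalizedAdditiveFit", "fit_additive_model"]

_MAX_IRLS = 30
_IRLS_TOL = 1e-7


@dataclass
class PenalizedAdditiveFit:
    """Result of one penalized additive fit (see ``fit_additive_model``)."""

    family: str
    smooth: bool
    params: np.ndarray
    cov_params: np.ndarray
    intercept: float
    intercept_se: float
    edf_smooth: float
    edf_total: float
    term_stat: float
    term_stat_name: str
    term_p: float
    linear_coef: float | None
    linear_se: float | None
    aic: float
    deviance: float
    loglik: float
    scale: float
    re_variance: float | None
    lambdas: dict[str, float]
    nobs: int
    n_groups: int
    converged: bool
    x_mean: float = 0.0
    _basis: object | None = field(default=None, repr=False)
    _slices: dict = field(default_factory=dict, repr=False)

    def predict_curve(self, x_new: np.ndarray) -> np.ndarray:
        """Population-level fitted trend (random intercepts at 0).

        Returns values on the response scale (probability for binomial).
        """
        x_new = np.asarray(x_new, dtype=float)
        eta = np.full(len(x_new), self.params[self._slices["intercept"]][0])
        if self.smooth:
            b = self._basis.transform(x_new[:, None])
            b = b - self._basis_colmeans
            eta = eta + b @ self.params[self._slices["smooth"]]
        else:
            eta = eta + (x_new - self.x_mean) * self.params[self._slices["linear"]][0]
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _build_design(x, groups, smooth, df, degree):
    n = len(x)
    cols = [np.ones((n, 1))]
    slices = {"intercept": slice(0, 1)}
    pen_blocks = []  # (slice, penalty matrix, name)
    pos = 1
    basis = None
    basis_colmeans = None
    x_mean = float(np.mean(x))
    if smooth:
        basis = BSplines(x[:, None], df=[df], degree=[degree],
                         include_intercept=False)
        b = basis.basis
        basis_colmeans = b.mean(axis=0)
        b = b - basis_colmeans
        cols.append(b)
        slices["smooth"] = slice(pos, pos + b.shape[1])
        pen_blocks.append((slices["smooth"], basis.penalty_matrices[0], "smooth"))
        pos += b.shape[1]
    else:
        cols.append((x - x_mean)[:, None])
        slices["linear"] = slice(pos, pos + 1)
        pos += 1
    n_groups = 0
    if groups is not None:
        levels, idx = np.unique(groups, return_inverse=True)
        n_groups = len(levels)
        z = np.zeros((n, n_groups))
        z[np.arange(n), idx] = 1.0
        cols.append(z)
        slices["group"] = slice(pos, pos + n_groups)
        pen_blocks.append((slices["group"], np.eye(n_groups), "group"))
        pos += n_groups
    X = np.hstack(cols)
    return X, slices, pen_blocks, basis, basis_colmeans, x_mean, n_groups


def _pirls(X, y, trials, family, S, beta0=None):
    """Penalized IRLS; returns (beta, W, z, deviance, converged)."""
    n, p = X.shape
    if family == "gaussian":
        XtX = X.T @ X
        beta = np.linalg.solve(XtX + S + 1e-10 * np.eye(p), X.T @ y)
        resid = y - X @ beta
        return beta, np.ones(n), y, float(resid @ resid), True
    w0 = trials
    if beta0 is not None:
        eta = np.clip(X @ beta0, -30, 30)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    else:
        mu = (y * w0 + 0.5) / (w0 + 1.0)
        eta = np.log(mu / (1.0 - mu))
    dev_old = np.inf
    converged = False
    beta = np.zeros(p)
    for _ in range(_MAX_IRLS):
        W = w0 * mu * (1.0 - mu)
        W = np.maximum(W, 1e-10)
        z = eta + (y - mu) / np.maximum(mu * (1.0 - mu), 1e-10)
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X + S + 1e-10 * np.eye(p), XtW @ z)
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        dev = _binom_deviance(y, mu, w0)
        if abs(dev - dev_old) < _IRLS_TOL * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    W = w0 * mu * (1.0 - mu)
    z = eta + (y - mu) / np.maximum(mu * (1.0 - mu), 1e-10)
    return beta, np.maximum(W, 1e-10), z, float(dev), converged


def _binom_deviance(y, mu, w0):
    def xlogy(a, b):
        return np.where(a > 0, a * np.log(np.maximum(b, 1e-300)), 0.0)

    s = w0 * y
    f = w0 * (1 - y)
    return float(2 * np.sum(
        xlogy(s, np.where(s > 0, s / (w0 * mu), 1.0))
        + xlogy(f, np.where(f > 0, f / (w0 * (1 - mu)), 1.0))
    ))


def _assemble_penalty(p, pen_blocks, lambdas):
    S = np.zeros((p, p))
    for (sl, mat, name), lam in zip(pen_blocks, lambdas):
        S[sl, sl] += lam * mat
    return S


def fit_additive_model(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray | None = None,
    family: str = "gaussian",
    trials: np.ndarray | None = None,
    smooth: bool = True,
    df: int = 10,
    degree: int = 3,
) -> PenalizedAdditiveFit:
    """Fit ``g(E y) = intercept + s(x) [+ random intercept per group]``.

    Parameters
    ----------
    y : response; for ``family='binomial'`` the proportion of successes,
        with ``trials`` the binomial denominators.
    x : the single continuous covariate (calendar day here).
    groups : optional labels for a ridge-penalized random intercept.
    smooth : fit a penalized B-spline of ``x`` (True) or the linear
        counterpart (False) — both through the same machinery so AIC values
        are directly comparable.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError("family must be 'gaussian' or 'binomial'")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if family == "binomial":
        trials = np.ones_like(y) if trials is None else np.asarray(trials, float)
    X, slices, pen_blocks, basis, basis_cm, x_mean, n_groups = _build_design(
        x, groups, smooth, df, degree)
    n, p = X.shape

    warm = {"beta": None}

    def crit(log_lams):
        lams = 10.0 ** np.asarray(log_lams)
        S = _assemble_penalty(p, pen_blocks, lams)
        beta, W, z, dev, _ = _pirls(X, y, trials, family, S,
                                    beta0=warm["beta"])
        warm["beta"] = beta
        XtW = X.T * W
        H = XtW @ X
        F = np.linalg.solve(H + S + 1e-10 * np.eye(p), H)
        edf = float(np.trace(F))
        if family == "gaussian":
            rss = dev
            denom = max(n - edf, 1e-3)
            return n * rss / denom**2
        return dev / n + 2.0 * edf / n  # UBRE up to a constant, scale = 1

    n_lams = len(pen_blocks)
    if n_lams:
        x0 = np.zeros(n_lams)
        res = optimize.minimize(
            crit, x0, method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-6, "maxfev": 60 * n_lams},
        )
        lams = 10.0 ** res.x
    else:
        lams = np.array([])

    S = _assemble_penalty(p, pen_blocks, lams)
    beta, W, z, dev, converged = _pirls(X, y, trials, family, S)
    XtW = X.T * W
    H = XtW @ X
    Hinv_pen = np.linalg.inv(H + S + 1e-10 * np.eye(p))
    F = Hinv_pen @ H
    edf_blocks = {name: float(np.trace(F[sl, sl]))
                  for (sl, _, name) in pen_blocks}
    edf_total = float(np.trace(F))
    if family == "gaussian":
        scale = dev / max(n - edf_total, 1e-3)
        loglik = -0.5 * n * (np.log(2 * np.pi * dev / n) + 1.0)
    else:
        scale = 1.0
        mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
        loglik = float(np.sum(
            stats.binom.logpmf(np.round(y * trials), np.round(trials),
                               np.clip(mu, 1e-10, 1 - 1e-10))))
    # +1 for the Gaussian scale parameter, matching mixed-model AIC usage
    k_scale = 1.0 if family == "gaussian" else 0.0
    aic = -2.0 * loglik + 2.0 * (edf_total + k_scale)
    Vb = Hinv_pen * scale

    intercept = float(beta[slices["intercept"]][0])
    intercept_se = float(np.sqrt(Vb[0, 0]))

    if smooth:
        sl = slices["smooth"]
        bs = beta[sl]
        Vs = Vb[sl, sl]
        edf_s = edf_blocks.get("smooth", float(len(bs)))
        r = max(1, int(round(edf_s)))
        # rank-truncated Wald statistic for the smooth block
        evals, evecs = np.linalg.eigh(Vs)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order][:r], evecs[:, order][:, :r]
        proj = evecs.T @ bs
        stat = float(proj @ (proj / np.maximum(evals, 1e-12)))
        if family == "binomial":
            term_p = float(stats.chi2.sf(stat, r))
            stat_name = "chi2"
        else:
            stat = stat / r
            term_p = float(stats.f.sf(stat, r, max(n - edf_total, 1.0)))
            stat_name = "F"
        linear_coef = linear_se = None
    else:
        sl = slices["linear"]
        linear_coef = float(beta[sl][0])
        linear_se = float(np.sqrt(Vb[sl, sl][0, 0]))
        tval = linear_coef / linear_se
        if family == "binomial":
            stat = tval**2
            term_p = float(stats.chi2.sf(stat, 1))
            stat_name = "chi2"
        else:
            stat = tval**2
            term_p = float(stats.f.sf(stat, 1, max(n - edf_total, 1.0)))
            stat_name = "F"
        edf_s = 1.0

    re_var = None
    if groups is not None:
        lam_g = lams[[nm for _, _, nm in pen_blocks].index("group")]
        re_var = float(scale / lam_g)

    fit = PenalizedAdditiveFit(
        family=family,
        smooth=smooth,
        params=beta,
        cov_params=Vb,
        intercept=intercept,
        intercept_se=intercept_se,
        edf_smooth=float(edf_s),
        edf_total=edf_total,
        term_stat=float(stat),
        term_stat_name=stat_name,
        term_p=term_p,
        linear_coef=linear_coef,
        linear_se=linear_se,
        aic=float(aic),
        deviance=float(dev),
        loglik=float(loglik),
        scale=float(scale),
        re_variance=re_var,
        lambdas={nm: float(l) for (_, _, nm), l in zip(pen_blocks, lams)},
        nobs=n,
        n_groups=n_groups,
        converged=bool(converged),
        x_mean=x_mean,
        _basis=basis,
        _slices=slices,
    )
    fit._basis_colmeans = basis_cm
    return fit
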