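"""General linear model solvers: ordinary least squares and AR-IRLS.

AR-IRLS iterates: fit, estimate a per-channel AR(p) model on the residuals
(order chosen by BIC via a Levinson-Durbin sweep), prewhiten data and design
with the AR filter, and refit with Tukey-bisquare robust weights, until the
coefficients stabilise.  Prewhitening makes the standard errors approximately
valid under serially correlated noise, where naive OLS is anticonservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

OLS = "ols"
AR_IRLS = "ar_irls"


@dataclass
class GLMFit:
    design: np.ndarray  # (samples, regressors)
    betas: np.ndarray  # (regressors, channels)
    se: np.ndarray  # (regressors, channels) standard errors
    residuals: np.ndarray  # (samples, channels), on the original scale
    solver: str
    ar_orders: list[int] | None = None
    ar_coefficients: list[np.ndarray] | None = None
    robust_weights: list[np.ndarray] | None = None

    def fitted(self) -> np.ndarray:
        return self.design @ self.betas


def _levinson_durbin(acov: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """All-order AR solutions from the autocovariance sequence.

    Returns per order p = 0..P the AR coefficient vector and the prediction
    error variance, in one recursion.
    """
    P = len(acov) - 1
    coeffs: list[np.ndarray] = [np.array([])]
    sigma2 = np.empty(P + 1)
    sigma2[0] = acov[0]
    a = np.array([])
    for p in range(1, P + 1):
        if sigma2[p - 1] <= 0:
            # perfectly predictable; stop extending
            for q in range(p, P + 1):
                coeffs.append(a.copy())
                sigma2[q] = max(sigma2[p - 1], 0.0)
            break
        k = (acov[p] - np.dot(a, acov[p - 1 : 0 : -1])) / sigma2[p - 1]
        a_new = np.concatenate([a - k * a[::-1], [k]]) if p > 1 else np.array([k])
        sigma2[p] = sigma2[p - 1] * (1 - k**2)
        coeffs.append(a_new)
        a = a_new
    return coeffs, sigma2


def select_ar_model(x: np.ndarray, max_order: int) -> np.ndarray:
    """AR coefficients of the BIC-best order (possibly empty = white noise)."""
    n = len(x)
    max_order = int(min(max_order, n // 4))
    if max_order < 1 or np.allclose(x, x[0]):
        return np.array([])
    xc = x - x.mean()
    acov = np.array(
        [np.dot(xc[: n - k], xc[k:]) / n for k in range(max_order + 1)]
    )
    if acov[0] <= 0:
        return np.array([])
    coeffs, sigma2 = _levinson_durbin(acov)
    with np.errstate(divide="ignore"):
        bic = n * np.log(np.maximum(sigma2, 1e-300)) + np.arange(max_order + 1) * np.log(n)
    return coeffs[int(np.argmin(bic))]


def _tukey_irls(
    X: np.ndarray,
    y: np.ndarray,
    c: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tukey-bisquare M-estimation by iteratively reweighted least squares.

    Returns (beta, standard errors, weights).  The scale is the MAD of the
    residuals; standard errors use the usual M-estimator sandwich
    ``s^2 * sum(psi^2)/(n-p) / (mean(psi'))^2 * (X'X)^-1``.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(n)
    for _ in range(max_iter):
        r = y - X @ beta
        s = 1.4826 * np.median(np.abs(r - np.median(r)))
        if s == 0:
            break
        u = r / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * max(1.0, np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new

    r = y - X @ beta
    s = 1.4826 * np.median(np.abs(r - np.median(r)))
    if s == 0:
        se = np.zeros(p)
    else:
        u = r / s
        uc = u / c
        inside = np.abs(uc) < 1
        psi = np.where(inside, u * (1 - uc**2) ** 2, 0.0)
        dpsi = np.where(inside, (1 - uc**2) * (1 - 5 * uc**2), 0.0)
        denom = np.mean(dpsi)
        if denom <= 0:
            denom = 1.0
        var_scale = s**2 * np.sum(psi**2) / (n - p) / denom**2
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * var_scale)
    return beta, se, w


def _prewhiten(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Apply the AR whitening filter e_t = x_t - sum_i a_i x_{t-i}."""
    if a.size == 0:
        return x
    b = np.concatenate([[1.0], -a])
    return lfilter(b, [1.0], x, axis=0)


def fit_glm(
    Y: np.ndarray,
    X: np.ndarray,
    solver: str = AR_IRLS,
    max_ar_order: int | None = None,
    robust: bool = True,
    tol: float = 1e-4,
    max_iter: int = 10,
) -> GLMFit:
    """Fit ``Y = X beta + eps`` per channel.

    Parameters
    ----------
    Y : (samples,) or (samples, channels)
    X : (samples, regressors) full-column-rank design
    solver : "ols" or "ar_irls"
    max_ar_order : AR order cap for prewhitening (default ceil(4 * 7.8125) = 32)
    robust : use Tukey-bisquare IRLS in the prewhitened refits

    NaN channels yield NaN betas.  Residuals are reported on the original
    (unwhitened) scale: ``Y - X beta``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than regressors")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (multicollinear regressors)")
    if max_ar_order is None:
        max_ar_order = 32
    n_ch = Y.shape[1]

    betas = np.full((p, n_ch), np.nan)
    se = np.full((p, n_ch), np.nan)
    residuals = np.full((n, n_ch), np.nan)
    ar_orders: list[int] = []
    ar_coeffs: list[np.ndarray] = []
    weights: list[np.ndarray] = []

    XtX_inv = np.linalg.inv(X.T @ X)
    for ch in range(n_ch):
        y = Y[:, ch]
        if np.any(np.isnan(y)):
            ar_orders.append(0)
            ar_coeffs.append(np.array([]))
            weights.append(np.array([]))
            continue
        beta = XtX_inv @ (X.T @ y)
        if solver == OLS:
            resid = y - X @ beta
            dof = n - p
            s2 = float(resid @ resid) / dof
            se_ch = np.sqrt(np.diag(XtX_inv) * s2)
            a = np.array([])
            w = np.ones(n)
        elif solver == AR_IRLS:
            a = np.array([])
            w = np.ones(n)
            se_ch = np.full(p, np.nan)
            for _ in range(max_iter):
                resid = y - X @ beta
                a = select_ar_model(resid, max_ar_order)
                yw = _prewhiten(y, a)
                Xw = _prewhiten(X, a)
                k = len(a)  # drop filter warm-up rows
                yw, Xw = yw[k:], Xw[k:]
                if robust:
                    beta_new, se_ch, w_in = _tukey_irls(Xw, yw)
                    w = np.ones(n)
                    w[k:] = w_in
                else:
                    beta_new, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
                    rw = yw - Xw @ beta_new
                    s2 = float(rw @ rw) / (len(yw) - p)
                    se_ch = np.sqrt(np.diag(np.linalg.inv(Xw.T @ Xw)) * s2)
                if np.max(np.abs(beta_new - beta)) < tol:
                    beta = beta_new
                    break
                beta = beta_new
            resid = y - X @ beta
        else:
            raise ValueError(f"unknown solver {solver!r}")

        betas[:, ch] = beta
        se[:, ch] = se_ch
        residuals[:, ch] = resid
        ar_orders.append(len(a))
        ar_coeffs.append(a)
        weights.append(w)

    return GLMFit(X, betas, se, residuals, solver, ar_orders, ar_coeffs, weights)
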