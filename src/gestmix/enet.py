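"""Elastic-net penalized logistic regression with per-term penalty masking.

Solves, for mixing parameter alpha and penalty level lambda,

    min_{b0, beta}  (1/n) sum_i [log(1+exp(eta_i)) - y_i eta_i]
                    + lambda * sum_j v_j (alpha |beta_j| + (1-alpha)/2 beta_j^2)

with eta = b0 + X beta and per-term penalty factors v_j in {0, 1}
(adjustment covariates carry v_j = 0 and are never shrunk). The
parameterization matches glmnet's, so lambda values are comparable.

The solver is IRLS with covariance-update coordinate descent: each
quadratic subproblem works on the p x p Gram matrix, so a fit costs
O(n p^2 + sweeps p^2), which keeps the nested bootstrap x MI x permutation
procedures of the stability-selection stage tractable. Columns are assumed
standardized by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnetFit", "fit_enet_logistic", "lambda_path", "cv_enet_logistic"]


@dataclass
class EnetFit:
    intercept: float
    coef: np.ndarray
    lam: float
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    cv_deviance: np.ndarray | None = None
    path: np.ndarray | None = None


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def fit_enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    penalty_mask: np.ndarray,
    beta0: float = 0.0,
    beta: np.ndarray | None = None,
    max_outer: int = 50,
    max_sweeps: int = 30,
    tol: float = 1e-6,
    dev_tol: float = 1e-8,
    coef_cap: float = 30.0,
) -> EnetFit:
    """Fit at a single lambda. ``penalty_mask`` True = penalized term.

    Warm starts via ``beta0``/``beta``. Complete separation is detected as
    coefficient blow-up and flagged (not raised); an all-zero column is an
    error.
    """
    n, p = X.shape
    v = penalty_mask.astype(float)
    col_var = X.var(axis=0)
    if np.any(col_var <= 0):
        raise ValueError("design contains a constant (zero-variance) column")
    b = np.zeros(p) if beta is None else beta.copy()
    b0 = float(beta0)
    warns: list[str] = []
    converged = False
    l1 = lam * alpha * v
    l2 = lam * (1.0 - alpha) * v

    eta = b0 + X @ b
    dev_prev = np.inf
    for _ in range(max_outer):
        dev = float(
            np.mean(np.logaddexp(0.0, eta) - y * eta)
            + np.sum(l1 * np.abs(b))
            + 0.5 * np.sum(l2 * b * b)
        )
        if dev_prev - dev < dev_tol * (abs(dev_prev) + 0.1):
            # objective flat: either converged or creeping along a
            # separation direction; stop either way
            if np.max(np.abs(b), initial=0.0) > 0.5 * coef_cap:
                warns.append("possible complete separation: flat deviance at large coefficients")
            converged = True
            break
        dev_prev = dev
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        sw = w.mean()
        Xw = X * w[:, None]
        A = (X.T @ Xw) / n
        xw = Xw.mean(axis=0)
        c = (Xw.T @ z) / n
        zw = float((w * z).mean())
        Ad = np.diag(A).copy()

        b_old_outer = b.copy()
        for _s in range(max_sweeps):
            max_delta = 0.0
            b0_new = (zw - xw @ b) / sw
            b0 = b0_new
            Ab = A @ b
            for j in range(p):
                g = c[j] - b0 * xw[j] - Ab[j] + Ad[j] * b[j]
                bj = _soft(g, l1[j]) / (Ad[j] + l2[j])
                d = bj - b[j]
                if d != 0.0:
                    Ab += A[:, j] * d
                    b[j] = bj
                    md = abs(d) * np.sqrt(Ad[j])
                    if md > max_delta:
                        max_delta = md
            if max_delta < tol:
                break
        eta = b0 + X @ b
        if np.max(np.abs(b - b_old_outer), initial=0.0) < 10 * tol:
            converged = True
            break
        if np.max(np.abs(b), initial=0.0) > coef_cap:
            warns.append("possible complete separation: coefficients capped out")
            break
    if not converged and not warns:
        warns.append("IRLS did not fully converge")
    return EnetFit(intercept=b0, coef=b, lam=lam, converged=converged, warnings=warns)


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    penalty_mask: np.ndarray,
    nlam: int = 20,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Descending lambda path from the smallest lambda that zeroes every
    penalized term (null-model gradient rule) down to min_ratio times it."""
    n = X.shape[0]
    ybar = y.mean()
    g = np.abs(X.T @ (y - ybar)) / n
    a = max(alpha, 1e-3)
    lam_max = float(g[penalty_mask].max()) / a
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, nlam)


def _stratified_folds(
    y: np.ndarray, nfolds: int, rng: np.random.Generator
) -> np.ndarray:
    fold = np.empty(len(y), dtype=int)
    for level in (0, 1):
        idx = np.flatnonzero(y == level)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % nfolds
    return fold


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    # 2/n * sum[log(1+e^eta) - y eta], numerically stable
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def cv_enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    penalty_mask: np.ndarray,
    nlam: int = 20,
    min_ratio: float = 0.01,
    nfolds: int = 5,
    seed: int | np.random.Generator = 0,
    **fit_kwargs,
) -> EnetFit:
    """Choose lambda by k-fold cross-validated deviance (lambda.min rule)
    and refit on the full data. Folds are stratified on the outcome."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lams = lambda_path(X, y, alpha, penalty_mask, nlam=nlam, min_ratio=min_ratio)
    fold = _stratified_folds(y, nfolds, rng)
    dev = np.zeros((nfolds, len(lams)))
    for f in range(nfolds):
        tr = fold != f
        va = ~tr
        Xtr, ytr = X[tr], y[tr]
        b0, b = 0.0, None
        for li, lam in enumerate(lams):
            fit = fit_enet_logistic(
                Xtr, ytr, alpha, lam, penalty_mask, beta0=b0, beta=b, **fit_kwargs
            )
            b0, b = fit.intercept, fit.coef
            dev[f, li] = _deviance(fit.intercept + X[va] @ fit.coef, y[va])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    b0, b = 0.0, None
    final = None
    for lam in lams[: best + 1]:
        final = fit_enet_logistic(
            X, y, alpha, lam, penalty_mask, beta0=b0, beta=b, **fit_kwargs
        )
        b0, b = final.intercept, final.coef
    assert final is not None
    final.cv_deviance = mean_dev
    final.path = lams
    return final
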