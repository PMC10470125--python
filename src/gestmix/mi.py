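"""Multiple imputation for incomplete multivariate-normal data, with bounds
for left-censored cells, plus Rubin's-rules pooling utilities.

The imputation model is a joint multivariate normal over the outcome,
ln-scale exposures and covariates (binary variables coded 0/1 and imputed
by thresholding). Each of the M completed datasets comes from a
bootstrap-EM draw: resample rows, fit the MVN by EM, then draw every
missing cell from its conditional normal given the observed cells of its
row. Cells censored below a detection/quantification limit are drawn by
rejection inside their (lower, upper) bounds, falling back to a univariate
truncated-normal conditional draw after a retry cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MIError",
    "EMResult",
    "ImputationSet",
    "PooledEstimate",
    "em_mvn",
    "impute",
    "rubin_pool",
    "pool_lr_pvalues",
    "imputation_density_table",
]


class MIError(ValueError):
    pass


class EMConvergenceError(MIError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: list[float]
    n_iter: int
    converged: bool


@dataclass
class ImputationSet:
    """M completed copies of an exposure/covariate table.

    Originally observed cells are identical across datasets; bounded imputed
    cells lie inside their bounds in every dataset.
    """

    datasets: list[pd.DataFrame]
    M: int
    seed: int | None = None
    bounds: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)
    em_iterations: list[int] = field(default_factory=list)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M point estimates and variances."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    M: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        if self.total_var == 0:
            return self.point, self.point
        t = (
            sps.norm.ppf(0.5 + level / 2)
            if not np.isfinite(self.df)
            else sps.t.ppf(0.5 + level / 2, self.df)
        )
        h = t * self.se
        return self.point - h, self.point + h


def _pattern_groups(mask: np.ndarray):
    """Group row indices by missingness pattern (mask True = missing)."""
    if mask.shape[0] == 0:
        return
    order = np.lexsort(mask.T[::-1])
    sorted_mask = mask[order]
    change = np.any(sorted_mask[1:] != sorted_mask[:-1], axis=1)
    starts = np.concatenate([[0], np.flatnonzero(change) + 1, [len(order)]])
    for a, b in zip(starts[:-1], starts[1:]):
        yield sorted_mask[a], order[a:b]


def em_mvn(
    X: np.ndarray | pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-8,
) -> EMResult:
    """ML estimation of (mean, covariance) of an MVN from incomplete data.

    Standard EM with missingness-pattern grouping; the observed-data
    log-likelihood is non-decreasing and convergence is declared when its
    relative change falls below ``tol``. Covariances are ML (denominator n).
    Singular observed blocks are ridge-stabilized with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mask = np.isnan(X)
    if mask.all(axis=0).any():
        raise MIError("a column is entirely missing")
    if n < 2:
        raise MIError("need at least 2 rows")

    col_mean = np.nanmean(X, axis=0)
    X0 = np.where(mask, col_mean, X)
    mu = X0.mean(axis=0)
    S = np.cov(X0, rowvar=False, bias=True) + ridge * np.eye(p)

    trace: list[float] = []
    ridged = False
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        loglik = 0.0
        for pat, rows in _pattern_groups(mask):
            o = np.flatnonzero(~pat)
            m = np.flatnonzero(pat)
            Xo = X[np.ix_(rows, o)]
            Soo = S[np.ix_(o, o)]
            try:
                Lo = np.linalg.cholesky(Soo)
            except np.linalg.LinAlgError:
                if not ridged:
                    warnings.warn("singular observed covariance block; ridge added")
                    ridged = True
                Lo = np.linalg.cholesky(Soo + 1e-6 * np.eye(len(o)))
            dev = Xo - mu[o]
            sol = np.linalg.solve(Lo, dev.T)  # (|o|, n_rows)
            loglik += float(
                -0.5 * (sol**2).sum()
                - len(rows)
                * (np.log(np.diag(Lo)).sum() + 0.5 * len(o) * np.log(2 * np.pi))
            )
            Xfill = X[rows].copy()
            if len(m) > 0:
                B = np.linalg.solve(Lo.T, np.linalg.solve(Lo, S[np.ix_(o, m)]))
                cond_mean = mu[m] + dev @ B
                Xfill[:, m] = cond_mean
                C = S[np.ix_(m, m)] - S[np.ix_(m, o)] @ B
                sum_xx[np.ix_(m, m)] += len(rows) * C
            sum_x += Xfill.sum(axis=0)
            sum_xx += Xfill.T @ Xfill
        mu = sum_x / n
        S = sum_xx / n - np.outer(mu, mu)
        S = 0.5 * (S + S.T) + ridge * np.eye(p)
        trace.append(loglik)
        if it > 1:
            prev = trace[-2]
            if abs(loglik - prev) <= tol * (abs(prev) + 1e-12):
                return EMResult(mu, S, trace, it, True)
    if not mask.any():
        # complete data: one pass is exact ML
        return EMResult(mu, S, trace, 1, True)
    raise EMConvergenceError(f"EM did not converge in {max_iter} iterations", trace)


def _conditional_draw(
    X: np.ndarray,
    mask: np.ndarray,
    mu: np.ndarray,
    S: np.ndarray,
    bounds_arr: dict[tuple[int, int], tuple[float, float]],
    rng: np.random.Generator,
    max_retry: int = 100,
) -> np.ndarray:
    """Draw missing cells from their conditional normals; honor bounds by
    row-wise rejection, then univariate truncated-normal fallback."""
    out = X.copy()
    for pat, rows in _pattern_groups(mask):
        m = np.flatnonzero(pat)
        if len(m) == 0:
            continue
        o = np.flatnonzero(~pat)
        Soo = S[np.ix_(o, o)] + 1e-10 * np.eye(len(o))
        B = np.linalg.solve(Soo, S[np.ix_(o, m)])
        cond_mean = mu[m] + (X[np.ix_(rows, o)] - mu[o]) @ B
        C = S[np.ix_(m, m)] - S[np.ix_(m, o)] @ B
        C = 0.5 * (C + C.T) + 1e-10 * np.eye(len(m))
        Lc = np.linalg.cholesky(C)
        draws = cond_mean + rng.standard_normal((len(rows), len(m))) @ Lc.T

        lowers = np.full((len(rows), len(m)), -np.inf)
        uppers = np.full((len(rows), len(m)), np.inf)
        for ri, row in enumerate(rows):
            for mi, col in enumerate(m):
                b = bounds_arr.get((int(row), int(col)))
                if b is not None:
                    lowers[ri, mi], uppers[ri, mi] = b
        bad = ((draws < lowers) | (draws > uppers)).any(axis=1)
        tries = 0
        while bad.any() and tries < max_retry:
            idx = np.flatnonzero(bad)
            draws[idx] = cond_mean[idx] + rng.standard_normal(
                (len(idx), len(m))
            ) @ Lc.T
            bad = ((draws < lowers) | (draws > uppers)).any(axis=1)
            tries += 1
        if bad.any():
            # Truncated univariate conditional fallback, given observed cells
            # and the other (already drawn) missing cells of the row.
            sd = np.sqrt(np.diag(C))
            for ri in np.flatnonzero(bad):
                for mi in range(len(m)):
                    lo, hi = lowers[ri, mi], uppers[ri, mi]
                    if not (np.isfinite(lo) or np.isfinite(hi)):
                        continue
                    a = (lo - cond_mean[ri, mi]) / sd[mi]
                    b = (hi - cond_mean[ri, mi]) / sd[mi]
                    draws[ri, mi] = sps.truncnorm.rvs(
                        a, b, loc=cond_mean[ri, mi], scale=sd[mi], random_state=rng
                    )
            if ((draws < lowers) | (draws > uppers)).any():
                raise MIError("bounded imputation violated bounds after fallback")
        out[np.ix_(rows, m)] = draws
    return out


def impute(
    table: pd.DataFrame,
    M: int = 20,
    bounds: dict[tuple[int, str], tuple[float, float]] | None = None,
    seed: int = 0,
    binary_columns: list[str] | None = None,
    columns: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ImputationSet:
    """Bootstrap-EM multiple imputation.

    ``bounds`` maps (row label, column name) to ln-scale (lower, upper)
    limits of left-censored cells. ``binary_columns`` are drawn continuous
    and thresholded at 0.5. Columns not listed in ``columns`` (default: all
    numeric) are carried through untouched. Reproducible for a fixed seed.
    """
    if M < 2:
        raise MIError("M must be >= 2")
    bounds = bounds or {}
    cols = columns or [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    cols = [c for c in cols if c != "subject_id"]
    binary_columns = binary_columns if binary_columns is not None else [
        c for c in cols if set(table[c].dropna().unique()) <= {0.0, 1.0}
    ]
    X = table[cols].to_numpy(dtype=float)
    mask = np.isnan(X)
    col_pos = {c: j for j, c in enumerate(cols)}
    row_pos = {lab: i for i, lab in enumerate(table.index)}
    bounds_arr: dict[tuple[int, int], tuple[float, float]] = {}
    for (row, col), b in bounds.items():
        if col in col_pos and row in row_pos:
            i, j = row_pos[row], col_pos[col]
            if not mask[i, j]:
                continue  # cell was observed after all
            bounds_arr[(i, j)] = b

    rng = np.random.default_rng(seed)
    n = len(table)
    datasets: list[pd.DataFrame] = []
    em_iters: list[int] = []
    for _ in range(M):
        if mask.any():
            boot = rng.integers(0, n, size=n)
            em = em_mvn(X[boot], tol=tol, max_iter=max_iter)
            em_iters.append(em.n_iter)
            filled = _conditional_draw(X, mask, em.mean, em.cov, bounds_arr, rng)
        else:
            filled = X.copy()
            em_iters.append(0)
        dfm = table.copy()
        dfm[cols] = filled
        for c in binary_columns:
            j = col_pos[c]
            imputed_rows = mask[:, j]
            if imputed_rows.any():
                dfm.loc[table.index[imputed_rows], c] = (
                    filled[imputed_rows, j] >= 0.5
                ).astype(float)
        datasets.append(dfm)
    return ImputationSet(
        datasets=datasets, M=M, seed=seed, bounds=dict(bounds), em_iterations=em_iters
    )


def imputation_density_table(
    original: pd.DataFrame, imputations: ImputationSet, n_grid: int = 100
) -> pd.DataFrame:
    """Plot-ready observed-vs-imputed density overlay per imputed variable.

    Gaussian kernel density estimates of the observed values and of the
    pooled imputed values, evaluated on a common grid — the standard visual
    check that imputations look distributionally reasonable.
    """
    rows = []
    for col in original.columns:
        if not pd.api.types.is_numeric_dtype(original[col]):
            continue
        miss = original[col].isna()
        if not miss.any():
            continue
        obs = original.loc[~miss, col].to_numpy(dtype=float)
        imp = np.concatenate(
            [d.loc[miss, col].to_numpy(dtype=float) for d in imputations.datasets]
        )
        if len(np.unique(obs)) < 3 or len(np.unique(imp)) < 2:
            continue  # binary or near-degenerate: densities uninformative
        lo = min(obs.min(), imp.min())
        hi = max(obs.max(), imp.max())
        grid = np.linspace(lo, hi, n_grid)
        k_obs = sps.gaussian_kde(obs)(grid)
        k_imp = sps.gaussian_kde(imp)(grid)
        for g, a, b in zip(grid, k_obs, k_imp):
            rows.append(
                {"variable": col, "x": g, "density_observed": a, "density_imputed": b}
            )
    return pd.DataFrame(rows)


def rubin_pool(
    points, variances, df_com: float | None = None
) -> PooledEstimate:
    """Combine M estimates by Rubin's rules.

    point = mean; W = mean within variance; B = between variance;
    T = W + (1+1/M)B. Degrees of freedom use the Barnard-Rubin small-sample
    formula when ``df_com`` (complete-data df) is given, else the classic
    large-sample formula.
    """
    q = np.asarray(points, dtype=float)
    u = np.asarray(variances, dtype=float)
    M = len(q)
    if M < 2:
        raise MIError("rubin_pool needs M >= 2 estimates")
    if (u < 0).any():
        raise MIError("variances must be nonnegative")
    point = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    if B <= 0 or T <= 0:
        df = np.inf
    else:
        r = (1.0 + 1.0 / M) * B
        with np.errstate(over="ignore"):
            df_old = float((M - 1) * np.square(1.0 + np.float64(W) / np.float64(r)))
        if df_com is None or not np.isfinite(df_com):
            df = df_old
        else:
            gamma = r / T
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - gamma)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledEstimate(point, W, B, T, float(df), M)


def pool_lr_pvalues(statistics, df: int) -> float:
    """Pool M likelihood-ratio chi-square statistics into one p-value (D2).

    Uses the mean-statistic combination with a between-imputation
    correction: r = (1+1/M) var(sqrt(d)); D2 = (dbar/k - (M+1)/(M-1) r) /
    (1 + r) referred to an F(k, nu) distribution with
    nu = k^(-3/M) (M-1) (1 + 1/r)^2.
    """
    d = np.asarray(statistics, dtype=float)
    if df <= 0:
        raise MIError("df must be positive")
    M = len(d)
    if M == 1:
        return float(sps.chi2.sf(d[0], df))
    dbar = float(d.mean())
    r = (1.0 + 1.0 / M) * float(np.var(np.sqrt(np.clip(d, 0, None)), ddof=1))
    if r <= 0:
        return float(sps.chi2.sf(dbar, df))
    D2 = (dbar / df - (M + 1.0) / (M - 1.0) * r) / (1.0 + r)
    if D2 <= 0:
        return 1.0
    nu = df ** (-3.0 / M) * (M - 1.0) * (1.0 + 1.0 / r) ** 2
    return float(sps.f.sf(D2, df, nu))
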