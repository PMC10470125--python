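"""Quantile g-computation of joint mixture effects.

Each mixture member is scored into q quantile categories (0..q-1); a
logistic model of the outcome on all member scores plus covariates gives
the joint effect psi = sum of member coefficients — the change in log-odds
when every member rises one quantile simultaneously. Member weights are the
sign-partitioned relative contributions (positive and negative partitions
each normalized to 1). Estimates are pooled across imputations by Rubin's
rules; the bootstrap variant adds nonlinear index terms and supplied
interaction terms and estimates a marginal psi by g-computation over the
counterfactual joint-quantile grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mi import ImputationSet, PooledEstimate, rubin_pool
from .specs import (
    ADJUSTMENT_COVARIATES,
    ESSENTIAL_ELEMENTS,
    METALS,
    SpecError,
    TOXIC_METALS,
)

__all__ = [
    "MixtureSpec",
    "MixtureResult",
    "quantize",
    "qgcomp_core",
    "qgcomp_boot",
    "leave_one_out",
]

_NAMED_MIXTURES = {
    "MixAll": list(METALS),
    "MixTox": list(TOXIC_METALS),
    "MixEssential": list(ESSENTIAL_ELEMENTS),
}


@dataclass(frozen=True)
class MixtureSpec:
    """A named or custom mixture of analytes scored into q quantiles."""

    name: str
    members: tuple[str, ...] = ()
    q: int = 4
    covariates: tuple[str, ...] = tuple(ADJUSTMENT_COVARIATES)

    def __post_init__(self) -> None:
        if self.name in _NAMED_MIXTURES:
            expected = _NAMED_MIXTURES[self.name]
            if self.members and sorted(self.members) != sorted(expected):
                raise SpecError(f"{self.name} members must be {expected}")
            object.__setattr__(self, "members", tuple(expected))
        elif not self.members:
            raise SpecError("custom mixture needs explicit members")
        if self.q < 2:
            raise SpecError("q must be >= 2")

    @staticmethod
    def named(name: str, q: int = 4) -> "MixtureSpec":
        return MixtureSpec(name=name, q=q)


@dataclass
class MixtureResult:
    mixture: str
    members: tuple[str, ...]
    psi: PooledEstimate  # pooled joint log-odds per one-quantile increase
    or_per_quantile: float
    ci_low: float
    ci_high: float
    weights: pd.DataFrame  # member, sign, weight
    variant: str = "core"
    psi_quadratic: PooledEstimate | None = None
    per_imputation_psi: list[float] = field(default_factory=list)


def quantize(values, q: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Score values into quantile categories 0..q-1.

    Cut-points are the j/q percentiles (linear interpolation); a value equal
    to a cut-point falls in the lower category. Returns (scores, cutpoints).
    Monotone and invariant to strictly increasing transforms.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantize requires complete values; impute first")
    if len(np.unique(x)) < q:
        raise ValueError(f"fewer than q={q} distinct values")
    cuts = np.percentile(x, [100.0 * j / q for j in range(1, q)])
    scores = np.searchsorted(cuts, x, side="left")
    return scores.astype(float), cuts


def _member_block_variance(cov: np.ndarray, idx: list[int]) -> float:
    block = cov[np.ix_(idx, idx)]
    return float(block.sum())


def _fit_quantized(
    d: pd.DataFrame, mixture: MixtureSpec, extra_cols: dict[str, np.ndarray] | None = None
):
    scores = {}
    for m in mixture.members:
        s, _ = quantize(d[m].to_numpy(), mixture.q)
        scores[m] = s
    cols = [scores[m] for m in mixture.members]
    names = list(mixture.members)
    if extra_cols:
        for nm, col in extra_cols.items():
            cols.append(col)
            names.append(nm)
    for c in mixture.covariates:
        cols.append(d[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack([np.ones(len(d))] + cols)
    y = d["case"].to_numpy(dtype=float)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        # collinear quantized members: ridge-stabilized refit
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-6, L1_wt=0.0
        )
    return res, names, scores


def qgcomp_core(imputations: ImputationSet, mixture: MixtureSpec) -> MixtureResult:
    """Conditional quantile-g-computation estimate of the joint mixture
    effect, pooled across imputations.

    Per imputation, psi_m = sum of member coefficients with variance from
    the full member-block covariance; pooling by Rubin's rules. Weights are
    computed from the imputation-averaged coefficients and partitioned by
    sign, each partition summing to 1.
    """
    psis, vars_, coef_stack = [], [], []
    for d in imputations.datasets:
        res, names, _ = _fit_quantized(d, mixture)
        idx = [1 + names.index(m) for m in mixture.members]
        coefs = np.array([res.params[j] for j in idx])
        psis.append(float(coefs.sum()))
        cov = np.asarray(res.cov_params()) if hasattr(res, "cov_params") else None
        if cov is not None and cov.ndim == 2:
            vars_.append(_member_block_variance(cov, idx))
        else:
            vars_.append(float("nan"))
        coef_stack.append(coefs)
    pe = rubin_pool(psis, vars_)
    lo, hi = pe.ci()
    mean_coefs = np.mean(coef_stack, axis=0)
    weights = _sign_weights(mixture.members, mean_coefs)
    return MixtureResult(
        mixture=mixture.name,
        members=mixture.members,
        psi=pe,
        or_per_quantile=float(np.exp(pe.point)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        weights=weights,
        variant="core",
        per_imputation_psi=psis,
    )


def _sign_weights(members, coefs) -> pd.DataFrame:
    rows = []
    pos = coefs[coefs > 0].sum()
    neg = -coefs[coefs < 0].sum()
    for m, c in zip(members, coefs):
        if c > 0:
            rows.append({"member": m, "sign": "positive", "weight": c / pos})
        elif c < 0:
            rows.append({"member": m, "sign": "negative", "weight": -c / neg})
        else:
            rows.append({"member": m, "sign": "zero", "weight": 0.0})
    out = pd.DataFrame(rows)
    out.attrs["positive_total"] = float(pos)
    out.attrs["negative_total"] = float(-neg)
    return out


def qgcomp_boot(
    imputations: ImputationSet,
    mixture: MixtureSpec,
    degree: int = 2,
    interactions: list[str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> MixtureResult:
    """Marginal (g-computation) variant with bootstrap confidence intervals.

    The conditional model regresses the outcome on member scores, optional
    squared scores (degree >= 2) and supplied interaction terms (member x
    member or member x covariate products of scores/values). The
    population-averaged log-odds at each counterfactual joint quantile
    a = 0..q-1 is the subject-mean linear predictor with every member set to
    a; psi comes from a degree-``degree`` least-squares fit of that average
    on a. With degree=1 and no interactions this reproduces the core psi
    exactly. CIs are normal-theory from the bootstrap variance, pooled
    across imputations by Rubin's rules.
    """
    if degree < 1:
        raise SpecError("degree must be >= 1")
    interactions = interactions or []
    rng = np.random.default_rng(seed)
    q = mixture.q

    def msm_coefs(d: pd.DataFrame) -> np.ndarray:
        extra: dict[str, np.ndarray] = {}
        scores = {m: quantize(d[m].to_numpy(), q)[0] for m in mixture.members}
        if degree >= 2:
            for m in mixture.members:
                extra[f"{m}^2"] = scores[m] ** 2
        for t in interactions:
            a, b = t.split(":")
            xa = scores[a] if a in scores else d[a].to_numpy(dtype=float)
            xb = scores[b] if b in scores else d[b].to_numpy(dtype=float)
            extra[t] = xa * xb
        res, names, _ = _fit_quantized(d, mixture, extra_cols=extra)
        beta = np.asarray(res.params)
        # counterfactual mean linear predictor at joint quantile a
        cov_vals = {c: d[c].to_numpy(dtype=float) for c in mixture.covariates}
        etas = []
        n = len(d)
        for a_val in range(q):
            eta = np.full(n, beta[0])
            for m in mixture.members:
                eta += beta[1 + names.index(m)] * a_val
            if degree >= 2:
                for m in mixture.members:
                    eta += beta[1 + names.index(f"{m}^2")] * a_val**2
            for t in interactions:
                ta, tb = t.split(":")
                xa = np.full(n, float(a_val)) if ta in scores else cov_vals.get(
                    ta, d[ta].to_numpy(dtype=float)
                )
                xb = np.full(n, float(a_val)) if tb in scores else cov_vals.get(
                    tb, d[tb].to_numpy(dtype=float)
                )
                eta += beta[1 + names.index(t)] * xa * xb
            for c in mixture.covariates:
                eta += beta[1 + names.index(c)] * cov_vals[c]
            etas.append(float(eta.mean()))
        A = np.vander(np.arange(q, dtype=float), degree + 1, increasing=True)
        coefs, *_ = np.linalg.lstsq(A, np.asarray(etas), rcond=None)
        return coefs  # [intercept, psi1, (psi2, ...)]

    psi1, psi1_var, psi2, psi2_var = [], [], [], []
    for d in imputations.datasets:
        point = msm_coefs(d)
        boots = np.empty((n_boot, degree + 1))
        n = len(d)
        case_idx = np.flatnonzero(d["case"].to_numpy() == 1)
        ctrl_idx = np.flatnonzero(d["case"].to_numpy() == 0)
        redrawn = 0
        for bi in range(n_boot):
            while True:
                take = rng.integers(0, n, size=n)
                if d["case"].to_numpy()[take].sum() > 0:
                    break
                redrawn += 1
            try:
                boots[bi] = msm_coefs(d.iloc[take].reset_index(drop=True))
            except ValueError:
                # degenerate quantiles in a bootstrap resample: redraw from
                # a case/control-balanced resample
                take = np.concatenate(
                    [
                        rng.choice(case_idx, len(case_idx), replace=True),
                        rng.choice(ctrl_idx, len(ctrl_idx), replace=True),
                    ]
                )
                boots[bi] = msm_coefs(d.iloc[take].reset_index(drop=True))
        psi1.append(float(point[1]))
        psi1_var.append(float(boots[:, 1].var(ddof=1)))
        if degree >= 2:
            psi2.append(float(point[2]))
            psi2_var.append(float(boots[:, 2].var(ddof=1)))
    pe = rubin_pool(psi1, psi1_var)
    lo, hi = pe.ci()
    pe2 = rubin_pool(psi2, psi2_var) if degree >= 2 else None
    # weights from a core fit on the same data
    core = qgcomp_core(imputations, mixture)
    return MixtureResult(
        mixture=mixture.name,
        members=mixture.members,
        psi=pe,
        or_per_quantile=float(np.exp(pe.point)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        weights=core.weights,
        variant="boot",
        psi_quadratic=pe2,
        per_imputation_psi=psi1,
    )


def leave_one_out(
    imputations: ImputationSet, mixture: MixtureSpec, member: str
) -> MixtureResult:
    """Core estimate for the mixture with ``member`` removed."""
    if member not in mixture.members:
        raise SpecError(f"{member} not in mixture {mixture.name}")
    remaining = tuple(m for m in mixture.members if m != member)
    if len(remaining) < 1:
        raise SpecError("cannot remove the only member of a mixture")
    sub = MixtureSpec(
        name=f"{mixture.name}-minus-{member}",
        members=remaining,
        q=mixture.q,
        covariates=mixture.covariates,
    )
    return qgcomp_core(imputations, sub)
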