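"""Synthetic nested case-control cohort generator.

Latent analyte concentrations follow a Gaussian copula with log-normal
marginals calibrated to arithmetic means/SDs; covariates are independent
draws matched to printed margins; case status follows a logistic model and
the final sample is drawn as an exact-count case-control subsample.
Analytical-round batch effects, QC reference replicates, below-limit
censoring and round-specific missingness are layered on top while the
uncensored truth is retained for recovery tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .specs import (
    METALS,
    BatchEffectSpec,
    CorrelationSpec,
    CovariateSpec,
    MarginalSpec,
    MissingSpec,
    OutcomeModelSpec,
    SpecError,
    default_batch,
    default_correlations,
    default_covariates,
    default_marginals,
    default_missing,
    default_outcome,
)

__all__ = [
    "SyntheticCohort",
    "lognormal_params_from_moments",
    "spearman_to_pearson",
    "correlation_matrix",
    "simulate_population",
    "generate_cohort",
    "apply_batch_effects",
    "censor_and_missing",
    "simulate",
]


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Invert arithmetic (mean, sd) to the (mu, sigma) of ln X.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2, so that the
    resulting log-normal has exactly the requested arithmetic moments.
    """
    if not mean > 0:
        raise SpecError("lognormal mean must be > 0")
    if sd < 0:
        raise SpecError("lognormal sd must be >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: the latent normal correlation that yields
    Spearman rho_s is 2 sin(pi rho_s / 6)."""
    if not -1.0 <= rho_s <= 1.0:
        raise SpecError(f"spearman rho {rho_s} outside [-1,1]")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def correlation_matrix(correlations: CorrelationSpec, metals: list[str] = METALS) -> np.ndarray:
    """Latent Pearson correlation matrix implied by a CorrelationSpec.

    Non-PSD matrices are repaired by eigenvalue clipping (with a warning) or
    rejected, per ``correlations.on_nonpsd``.
    """
    index = {m: i for i, m in enumerate(metals)}
    R = np.eye(len(metals))
    for a, b, rho_s in correlations.pairs:
        if a not in index or b not in index:
            raise SpecError(f"correlation pair ({a},{b}) names unknown analyte")
        r = spearman_to_pearson(rho_s)
        R[index[a], index[b]] = R[index[b], index[a]] = r
    eigval = np.linalg.eigvalsh(R)
    if eigval.min() < -1e-10:
        if correlations.on_nonpsd == "error":
            raise SpecError("implied Pearson correlation matrix is not PSD")
        warnings.warn("correlation matrix not PSD; repaired by eigenvalue clipping")
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


@dataclass
class SyntheticCohort:
    """A generated cohort: latent truth, observed (degraded) table, QC table.

    ``truth`` holds the uncensored, batch-free concentrations plus case
    status and covariates; ``observed`` is what the analysis pipeline sees;
    ``missing_reasons`` maps each missing exposure cell to its cause
    (below_lod / below_loq / not_analysed).
    """

    truth: pd.DataFrame
    observed: pd.DataFrame | None = None
    qc: pd.DataFrame | None = None
    missing_reasons: pd.DataFrame | None = None
    metal_betas: dict[str, float] = field(default_factory=dict)
    covariate_betas: dict[str, float] = field(default_factory=dict)
    seed: int | None = None


def _draw_covariates(spec: CovariateSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd, lower) in spec.continuous.items():
        x = rng.normal(mean, sd, size=n)
        bad = x < lower
        while bad.any():  # resample-truncation at the lower support bound
            x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = x < lower
        cols[name] = x
    for name, p in spec.binary.items():
        cols[name] = (rng.random(n) < p).astype(float)
    return pd.DataFrame(cols)


def simulate_population(
    n: int,
    marginals: dict[str, MarginalSpec] | None = None,
    correlations: CorrelationSpec | None = None,
    covariate_spec: CovariateSpec | None = None,
    outcome_spec: OutcomeModelSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a source population of ``n`` subjects.

    Returns a frame with latent (uncensored, batch-free) concentrations in
    original units, covariates, the linear predictor and case status.
    """
    marginals = marginals if marginals is not None else default_marginals()
    correlations = correlations if correlations is not None else default_correlations()
    covariate_spec = covariate_spec if covariate_spec is not None else default_covariates()
    outcome_spec = outcome_spec if outcome_spec is not None else default_outcome()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    metals = [m for m in METALS if m in marginals]
    R = correlation_matrix(correlations, metals)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(metals)))
    Z = rng.standard_normal((n, len(metals))) @ L.T

    df = pd.DataFrame({"subject_id": np.arange(n)})
    for j, m in enumerate(metals):
        mu, sigma = lognormal_params_from_moments(marginals[m].mean, marginals[m].sd)
        df[m] = np.exp(mu + sigma * Z[:, j])

    cov = _draw_covariates(covariate_spec, n, rng)
    df = pd.concat([df, cov], axis=1)

    # Metal betas act per 1 SD of ln-concentration, i.e. directly on Z.
    eta = np.full(n, outcome_spec.intercept)
    zindex = {m: j for j, m in enumerate(metals)}
    for m, b in outcome_spec.metal_betas.items():
        if m not in zindex:
            raise SpecError(f"outcome beta for unknown analyte {m}")
        eta += b * Z[:, zindex[m]]
    for c, b in outcome_spec.covariate_betas.items():
        if c not in df.columns:
            raise SpecError(f"outcome beta for unknown covariate {c}")
        eta += b * df[c].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    df["case_propensity"] = p
    df["case"] = (rng.random(n) < p).astype(int)
    return df


def generate_cohort(
    marginals: dict[str, MarginalSpec] | None = None,
    correlations: CorrelationSpec | None = None,
    covariate_spec: CovariateSpec | None = None,
    outcome_spec: OutcomeModelSpec | None = None,
    seed: int = 0,
    n_source: int = 30_000,
) -> SyntheticCohort:
    """Generate a nested case-control cohort with exact case/control counts.

    A source population of ``n_source`` subjects is simulated; exactly
    ``n_cases`` cases and ``n_controls`` controls are then sampled without
    replacement, mirroring a registry-nested design (the source-population
    intercept is a nuisance under this design).
    """
    outcome_spec = outcome_spec if outcome_spec is not None else default_outcome()
    rng = np.random.default_rng(seed)
    pop = simulate_population(
        n_source, marginals, correlations, covariate_spec, outcome_spec, seed=rng
    )
    case_idx = np.flatnonzero(pop["case"].to_numpy() == 1)
    ctrl_idx = np.flatnonzero(pop["case"].to_numpy() == 0)
    if len(case_idx) < outcome_spec.n_cases:
        raise SpecError(
            f"source population yielded {len(case_idx)} cases "
            f"< requested {outcome_spec.n_cases}; increase n_source or intercept"
        )
    if len(ctrl_idx) < outcome_spec.n_controls:
        raise SpecError("source population yielded too few controls")
    take = np.concatenate(
        [
            rng.choice(case_idx, size=outcome_spec.n_cases, replace=False),
            rng.choice(ctrl_idx, size=outcome_spec.n_controls, replace=False),
        ]
    )
    take.sort()
    truth = pop.iloc[take].reset_index(drop=True)
    truth["subject_id"] = np.arange(len(truth))
    return SyntheticCohort(
        truth=truth,
        metal_betas=dict(outcome_spec.metal_betas),
        covariate_betas=dict(outcome_spec.covariate_betas),
        seed=seed,
    )


def _unit_mean_lognormal_noise(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    s2 = math.log1p(cv**2)
    return np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), size=size))


def apply_batch_effects(
    cohort: SyntheticCohort,
    batch_spec: BatchEffectSpec | None = None,
    seed: int = 0,
    marginals: dict[str, MarginalSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade the latent truth with per-round multiplicative bias and noise,
    and emit matching QC reference-replicate measurements.

    raw = truth x multiplier(round, metal) x noise; QC replicates measure a
    fixed reference concentration (the marginal mean, standing in for a
    certified reference material) under the same bias and noise. The truth
    table is left untouched. Returns (raw exposure table, QC table) and
    records the round assignment on ``cohort.truth['round']``.
    """
    batch_spec = batch_spec if batch_spec is not None else default_batch()
    marginals = marginals if marginals is not None else default_marginals()
    rng = np.random.default_rng(seed)
    truth = cohort.truth
    n = len(truth)
    metals = [m for m in METALS if m in truth.columns]

    rounds = np.asarray(
        rng.choice(batch_spec.rounds, size=n, p=batch_spec.proportions), dtype=object
    )
    n_lund = int(round(batch_spec.lund_fraction * n))
    if n_lund > 0:
        rounds[rng.choice(n, size=n_lund, replace=False)] = batch_spec.lund_label
    truth["round"] = rounds

    raw = truth[["subject_id", "case"]].copy()
    raw["round"] = rounds
    for m in metals:
        mult = np.array(
            [batch_spec.multiplier(r, m) for r in rounds], dtype=float
        )
        noise = _unit_mean_lognormal_noise(batch_spec.sample_noise_cv, n, rng)
        raw[m] = truth[m].to_numpy() * mult * noise

    qc_rows = []
    for r in batch_spec.all_rounds:
        for m in metals:
            ref = marginals[m].mean
            mult = batch_spec.multiplier(r, m)
            vals = ref * mult * _unit_mean_lognormal_noise(
                batch_spec.qc_noise_cv, batch_spec.qc_replicates, rng
            )
            for v in vals:
                qc_rows.append((r, m, v))
    qc = pd.DataFrame(qc_rows, columns=["round", "metal", "qc_value"])

    # Carry covariates through unchanged on the observed table.
    other = [c for c in truth.columns if c not in raw.columns and c not in metals]
    other = [c for c in other if c != "case_propensity"]
    for c in other:
        raw[c] = truth[c].to_numpy()
    return raw, qc


def censor_and_missing(
    raw: pd.DataFrame,
    marginals: dict[str, MarginalSpec] | None = None,
    missing_spec: MissingSpec | None = None,
    seed: int = 0,
    lund_label: str = "lund",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply left-censoring and round-specific/MCAR missingness.

    As below its LOD and Cd/Co below their LOQ become missing (reasons
    below_lod / below_loq); analytes not measured in the external round
    become missing with reason not_analysed; configured covariates get MCAR
    missingness. Returns (observed table, missing-reason table aligned on
    the exposure columns).
    """
    marginals = marginals if marginals is not None else default_marginals()
    missing_spec = missing_spec if missing_spec is not None else default_missing()
    rng = np.random.default_rng(seed)
    obs = raw.copy()
    metals = [m for m in METALS if m in obs.columns]
    reasons = pd.DataFrame("", index=obs.index, columns=metals, dtype=object)

    censor_rule = {"as": "lod", "cd": "loq", "co": "loq"}
    for m, which in censor_rule.items():
        if m not in obs.columns:
            continue
        limit = getattr(marginals[m], which)
        if limit is None or limit <= 0:
            continue
        below = obs[m].to_numpy() < limit
        reasons.loc[below, m] = "below_" + which
        obs.loc[below, m] = np.nan

    if "round" in obs.columns:
        in_lund = obs["round"].to_numpy() == lund_label
        for m in missing_spec.not_analysed_metals:
            if m in obs.columns:
                obs.loc[in_lund, m] = np.nan
                reasons.loc[in_lund, m] = "not_analysed"

    for cov, rate in missing_spec.covariate_mcar.items():
        if cov in obs.columns and rate > 0:
            drop = rng.random(len(obs)) < rate
            obs.loc[drop, cov] = np.nan
    return obs, reasons


def simulate(
    seed: int = 0,
    marginals: dict[str, MarginalSpec] | None = None,
    correlations: CorrelationSpec | None = None,
    covariate_spec: CovariateSpec | None = None,
    outcome_spec: OutcomeModelSpec | None = None,
    batch_spec: BatchEffectSpec | None = None,
    missing_spec: MissingSpec | None = None,
    n_source: int = 30_000,
) -> SyntheticCohort:
    """Full simulation convenience wrapper: cohort + batch effects + censoring."""
    marginals = marginals if marginals is not None else default_marginals()
    cohort = generate_cohort(
        marginals, correlations, covariate_spec, outcome_spec, seed=seed, n_source=n_source
    )
    raw, qc = apply_batch_effects(cohort, batch_spec, seed=seed + 1, marginals=marginals)
    lund = (batch_spec or default_batch()).lund_label
    observed, reasons = censor_and_missing(
        raw, marginals, missing_spec, seed=seed + 2, lund_label=lund
    )
    cohort.observed = observed
    cohort.qc = qc
    cohort.missing_reasons = reasons
    return cohort
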