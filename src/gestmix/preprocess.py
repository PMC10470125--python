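"""Batch normalization, winsorization, log transform and IQR utilities.

The analytical-round (batch) adjustment rescales each measured concentration
by the ratio of the pooled geometric mean of the QC reference replicates to
the geometric mean of the QC replicates of the round the sample was measured
in:

    M*_ij = M_ij * (geomean(QC_i, all rounds) / geomean(QC_i, round k)).

Winsorization then caps concentrations at the 1st/99th percentiles of the
pooled sample, and analyses proceed on the natural-log scale. Percentiles
use linear interpolation between closest ranks throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .specs import METALS, MarginalSpec

__all__ = [
    "PreprocessError",
    "AdjustedTable",
    "batch_adjust",
    "winsorize",
    "log_transform",
    "iqr_ln",
    "preprocess_table",
]


class PreprocessError(ValueError):
    pass


@dataclass
class AdjustedTable:
    """Preprocessed exposure table.

    ``df`` carries metal columns on the ln scale (if ``logged``) after batch
    adjustment and optional winsorization; ``factors`` maps (metal, round)
    to the applied batch-adjustment ratio; ``stats`` records per-metal
    p1/p99 winsorization caps and the ln-scale IQR; ``bounds`` holds the
    ln-scale (lower, upper) imputation bounds of left-censored cells.
    """

    df: pd.DataFrame
    factors: dict[tuple[str, str], float] = field(default_factory=dict)
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    bounds: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)
    winsorized: bool = True
    logged: bool = True


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def batch_adjust(exposures: pd.DataFrame, qc: pd.DataFrame) -> AdjustedTable:
    """Ratio-adjust concentrations for analytical-round variation.

    Every (metal, round) combination with at least one observed value must
    have QC replicates; QC values must be positive. Missing cells stay
    missing. With a single round the adjustment is the identity.
    """
    metals = [m for m in METALS if m in exposures.columns]
    if "round" not in exposures.columns:
        raise PreprocessError("exposure table lacks a 'round' column")
    if (qc["qc_value"] <= 0).any():
        bad = qc.loc[qc["qc_value"] <= 0].iloc[0]
        raise PreprocessError(
            f"nonpositive QC value for metal={bad['metal']} round={bad['round']}"
        )
    out = exposures.copy()
    factors: dict[tuple[str, str], float] = {}
    rounds_present = exposures["round"].unique()
    for m in metals:
        qm = qc[qc["metal"] == m]
        if qm.empty:
            raise PreprocessError(f"no QC coverage for metal={m}")
        pooled = _geomean(qm["qc_value"].to_numpy())
        per_round = {
            r: _geomean(g["qc_value"].to_numpy()) for r, g in qm.groupby("round")
        }
        obs = out[m].notna().to_numpy()
        for r in rounds_present:
            in_round = (out["round"] == r).to_numpy()
            if not (obs & in_round).any():
                factors[(m, str(r))] = np.nan
                continue
            if r not in per_round:
                raise PreprocessError(f"no QC coverage for metal={m} round={r}")
            f = pooled / per_round[r]
            factors[(m, str(r))] = f
            out.loc[obs & in_round, m] = out.loc[obs & in_round, m] * f
    return AdjustedTable(df=out, factors=factors, winsorized=False, logged=False)


def winsorize(values, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Cap values below/above the p_lo/p_hi percentiles at those percentiles.

    Percentiles are computed on the observed (non-missing) values with
    linear interpolation; missing values pass through unchanged.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise PreprocessError("winsorize needs at least 2 observed values")
    lo, hi = np.percentile(x[obs], [p_lo, p_hi])
    out = x.copy()
    out[obs] = np.clip(x[obs], lo, hi)
    return out


def log_transform(values) -> np.ndarray:
    """Elementwise natural log; missing passes through; nonpositive observed
    values are an error."""
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if (x[obs] <= 0).any():
        raise PreprocessError("log_transform: nonpositive observed value")
    out = np.full_like(x, np.nan)
    out[obs] = np.log(x[obs])
    return out


def iqr_ln(ln_values) -> float:
    """Interquartile range (75th - 25th percentile) of ln-scale values."""
    x = np.asarray(ln_values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 4:
        raise PreprocessError("iqr_ln needs at least 4 observed values")
    q25, q75 = np.percentile(x[obs], [25.0, 75.0])
    iqr = float(q75 - q25)
    if iqr <= 0:
        raise PreprocessError("degenerate exposure: IQR is 0")
    return iqr


def preprocess_table(
    exposures: pd.DataFrame,
    qc: pd.DataFrame,
    marginals: dict[str, MarginalSpec] | None = None,
    do_winsorize: bool = True,
    eps_factor: float = 0.1,
) -> AdjustedTable:
    """Full preprocessing: batch adjust -> winsorize -> ln transform.

    Also derives ln-scale imputation bounds for left-censored cells: the
    detection/quantification limit is carried through the same round
    adjustment factor as the measurements, the lower bound is
    ln(eps_factor * limit) (strictly positive support near zero).
    """
    from .specs import default_marginals

    marginals = marginals if marginals is not None else default_marginals()
    adj = batch_adjust(exposures, qc)
    metals = [m for m in METALS if m in adj.df.columns]
    for m in metals:
        vals = adj.df[m].to_numpy(dtype=float)
        if do_winsorize:
            lo, hi = np.percentile(vals[~np.isnan(vals)], [1.0, 99.0])
            vals = winsorize(vals)
        else:
            v = vals[~np.isnan(vals)]
            lo, hi = float(v.min()), float(v.max())
        ln = log_transform(vals)
        adj.df[m] = ln
        adj.stats[m] = {"p1": float(lo), "p99": float(hi), "iqr_ln": iqr_ln(ln)}
    adj.winsorized = do_winsorize
    adj.logged = True

    censor_rule = {"as": "lod", "cd": "loq", "co": "loq"}
    for m, which in censor_rule.items():
        if m not in metals:
            continue
        limit = getattr(marginals[m], which)
        if limit is None:
            continue
        miss = adj.df[m].isna().to_numpy()
        rounds = adj.df["round"].astype(str).to_numpy()
        for i in np.flatnonzero(miss):
            f = adj.factors.get((m, rounds[i]))
            if f is None or np.isnan(f):
                f = 1.0
            upper = limit * f
            adj.bounds[(int(adj.df.index[i]), m)] = (
                float(np.log(eps_factor * upper)),
                float(np.log(upper)),
            )
    return adj
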