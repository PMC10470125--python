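"""Elastic-net stability selection with permutation p-values and BH-FDR.

The procedure nests three stochastic layers: B bootstrap resamples of the
subjects (stratified to preserve the case count), M multiple imputations of
each resample, and one cross-validated elastic-net logistic fit per imputed
dataset. A term's selection probability P_sel is the mean, over resamples,
of the fraction of imputations in which its coefficient is nonzero at the
CV-chosen lambda. Permutation p-values compare the observed P_sel against
the P_sel distribution under K random permutations of the case labels
(each permutation rerunning a reduced stability selection).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .enet import EnetFit, cv_enet_logistic, fit_enet_logistic
from .mi import impute
from .specs import ADJUSTMENT_COVARIATES, AUXILIARY_COVARIATES, METALS

__all__ = [
    "DesignMatrix",
    "SelectionConfig",
    "build_design",
    "elastic_net_logistic",
    "stability_selection",
    "permutation_pvalues",
    "bh_thresholds",
    "selection_report",
]

#: Columns entering the imputation model inside the selection procedure.
IMPUTE_COLUMNS = ["case"] + METALS + ADJUSTMENT_COVARIATES + AUXILIARY_COVARIATES


@dataclass
class DesignMatrix:
    """Standardized design: term names, values, and per-term penalty flags."""

    terms: list[str]
    values: np.ndarray
    penalized_mask: np.ndarray
    standardization: dict[str, tuple[float, float]]

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class SelectionConfig:
    """Resampling and fit settings for one stability-selection run.

    Defaults are the full study-scale settings; tests and quick runs pass
    reduced values. ``p_cut``/``psel_cut`` define the selection rule
    (main-effect run: p <= 0.05 and P_sel > 0.6; interaction run uses
    p <= 0.1).
    """

    B: int = 200
    M: int = 20
    K: int = 1200
    B_perm: int = 20
    M_perm: int = 10
    alpha: float = 0.9
    nlam: int = 20
    nfolds: int = 5
    min_ratio: float = 0.01
    p_cut: float = 0.05
    psel_cut: float = 0.6
    include_interactions: bool = False

    def interaction_run(self) -> "SelectionConfig":
        return replace(self, include_interactions=True, p_cut=0.1)


def build_design(
    dataset: pd.DataFrame,
    include_interactions: bool = False,
    modifiers: tuple[str, ...] = ("sex", "education"),
) -> DesignMatrix:
    """Build the standardized design from one completed (imputed) dataset.

    Main effects: the 11 ln-scale analytes (penalized) plus the adjustment
    covariates (unpenalized). With interactions on, all pairwise
    analyte x analyte products plus analyte x modifier products are added
    (penalized), computed from the standardized parents; main effects stay
    in the design alongside their interactions.
    """
    metals = [m for m in METALS if m in dataset.columns]
    base = metals + ADJUSTMENT_COVARIATES
    std: dict[str, tuple[float, float]] = {}
    cols: dict[str, np.ndarray] = {}
    for name in base:
        x = dataset[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"column {name} has missing cells; impute first")
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError(f"column {name} is constant")
        std[name] = (mu, sd)
        cols[name] = (x - mu) / sd
    terms = list(base)
    penalized = [True] * len(metals) + [False] * len(ADJUSTMENT_COVARIATES)
    if include_interactions:
        for a, b in itertools.combinations(metals, 2):
            terms.append(f"{a}:{b}")
            cols[f"{a}:{b}"] = cols[a] * cols[b]
            penalized.append(True)
        for mod in modifiers:
            for m in metals:
                terms.append(f"{m}:{mod}")
                cols[f"{m}:{mod}"] = cols[m] * cols[mod]
                penalized.append(True)
    values = np.column_stack([cols[t] for t in terms])
    return DesignMatrix(
        terms=terms,
        values=values,
        penalized_mask=np.array(penalized),
        standardization=std,
    )


def elastic_net_logistic(
    design: DesignMatrix,
    y: np.ndarray,
    alpha: float = 0.9,
    lambda_rule: str = "cv_min",
    seed: int | np.random.Generator = 0,
    lam: float | None = None,
    nlam: int = 20,
    nfolds: int = 5,
    min_ratio: float = 0.01,
    fit_kwargs: dict | None = None,
) -> tuple[EnetFit, set[str]]:
    """Penalized logistic fit; returns the fit and the set of selected terms
    (nonzero coefficient at the chosen lambda)."""
    y = np.asarray(y, dtype=float)
    fit_kwargs = fit_kwargs or {}
    if lambda_rule == "fixed":
        if lam is None:
            raise ValueError("lambda_rule='fixed' requires lam")
        fit = fit_enet_logistic(
            design.values, y, alpha, lam, design.penalized_mask, **fit_kwargs
        )
    elif lambda_rule == "cv_min":
        fit = cv_enet_logistic(
            design.values,
            y,
            alpha,
            design.penalized_mask,
            nlam=nlam,
            nfolds=nfolds,
            min_ratio=min_ratio,
            seed=seed,
            **fit_kwargs,
        )
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    selected = {t for t, c in zip(design.terms, fit.coef) if c != 0.0}
    return fit, selected


def _stratified_resample(
    df: pd.DataFrame, rng: np.random.Generator, min_cases: int = 5
) -> np.ndarray:
    case = df["case"].to_numpy()
    ci = np.flatnonzero(case == 1)
    ki = np.flatnonzero(case == 0)
    if len(ci) < min_cases:
        raise ValueError(f"fewer than {min_cases} cases in the data")
    idx = np.concatenate(
        [rng.choice(ci, size=len(ci), replace=True), rng.choice(ki, size=len(ki), replace=True)]
    )
    return idx


def stability_selection(
    table: pd.DataFrame,
    bounds: dict[tuple[int, str], tuple[float, float]] | None = None,
    config: SelectionConfig | None = None,
    seed: int = 0,
    B: int | None = None,
    M: int | None = None,
) -> pd.Series:
    """Mean selection probability P_sel per penalized term.

    ``table`` is the preprocessed (ln-scale) exposure table with missing
    cells; imputation happens inside each bootstrap resample. Fit failures
    are counted on the returned Series' ``attrs['fit_failures']``.
    """
    cfg = config or SelectionConfig()
    B = B if B is not None else cfg.B
    M = M if M is not None else cfg.M
    bounds = bounds or {}
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    psel_terms: pd.Series | None = None
    freq_sum: np.ndarray | None = None
    failures = 0
    labels = np.asarray(table.index)
    for b in range(B):
        idx = _stratified_resample(table, rng)
        res = table.iloc[idx].reset_index(drop=True)
        res_bounds = {}
        for new_i, orig_pos in enumerate(idx):
            lab = labels[orig_pos]
            for m in ("as", "cd", "co"):
                bnd = bounds.get((lab, m))
                if bnd is not None:
                    res_bounds[(new_i, m)] = bnd
        imp_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        imp = impute(
            res,
            M=M,
            bounds=res_bounds,
            seed=imp_seed,
            columns=[c for c in IMPUTE_COLUMNS if c in res.columns],
        )
        sel_count: dict[str, int] = {}
        n_fits = 0
        for d in imp.datasets:
            design = build_design(d, include_interactions=cfg.include_interactions)
            try:
                _, selected = elastic_net_logistic(
                    design,
                    d["case"].to_numpy(),
                    alpha=cfg.alpha,
                    seed=rng,
                    nlam=cfg.nlam,
                    nfolds=cfg.nfolds,
                    min_ratio=cfg.min_ratio,
                    # selection only needs the sign pattern at the chosen
                    # lambda; loose solver settings keep the nested
                    # bootstrap x MI x permutation procedure tractable
                    fit_kwargs={
                        "dev_tol": 1e-6,
                        "tol": 1e-5,
                        "max_outer": 25,
                        "max_sweeps": 20,
                    },
                )
            except Exception:
                failures += 1
                continue
            n_fits += 1
            for t in selected:
                sel_count[t] = sel_count.get(t, 0) + 1
        if n_fits == 0:
            failures += 1
            continue
        pen_terms = [t for t, p in zip(design.terms, design.penalized_mask) if p]
        if freq_sum is None:
            freq_sum = np.zeros(len(pen_terms))
            psel_terms = pd.Series(0.0, index=pen_terms)
        freq_sum += np.array([sel_count.get(t, 0) / n_fits for t in pen_terms])
    if freq_sum is None:
        raise RuntimeError("every stability-selection resample failed")
    out = pd.Series(freq_sum / B, index=psel_terms.index, name="p_sel")
    out.attrs["fit_failures"] = failures
    return out


def permutation_pvalues(
    table: pd.DataFrame,
    observed_psel: pd.Series,
    bounds: dict[tuple[int, str], tuple[float, float]] | None = None,
    config: SelectionConfig | None = None,
    seed: int = 0,
    K: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values for P_sel under the global outcome-null.

    For each of K permutations the case labels are shuffled (breaking every
    exposure/covariate-outcome link) and a reduced stability selection
    (B_perm, M_perm) is rerun; p = (1 + #{null P_sel >= observed}) / (1+K).
    """
    cfg = config or SelectionConfig()
    K = K if K is not None else cfg.K
    if K < 19:
        raise ValueError("K must be >= 19 for a p <= 0.05 resolution")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    exceed = pd.Series(0, index=observed_psel.index, dtype=int)
    null = np.zeros((K, len(observed_psel)))
    for k in range(K):
        perm = table.copy()
        perm["case"] = rng.permutation(perm["case"].to_numpy())
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        psel_k = stability_selection(
            perm, bounds=bounds, config=cfg, seed=sub_seed, B=cfg.B_perm, M=cfg.M_perm
        )
        psel_k = psel_k.reindex(observed_psel.index).fillna(0.0)
        null[k] = psel_k.to_numpy()
        exceed += (psel_k >= observed_psel).astype(int)
    p = (1 + exceed) / (1 + K)
    out = pd.DataFrame({"p_sel": observed_psel, "p_perm": p})
    out.attrs["null_psel"] = null
    out.attrs["min_attainable_p"] = 1.0 / (1 + K)
    return out


def bh_thresholds(pvalues: pd.Series, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up: threshold_i = i * alpha / m for ascending
    p_(i); every p at or below the largest passing rank is a discovery."""
    p = pd.Series(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = p.sort_values().index
    thresh = pd.Series(
        [(i + 1) * fdr_alpha / m for i in range(m)], index=order, name="bh_threshold"
    )
    passing = p.loc[order].to_numpy() <= thresh.to_numpy()
    if passing.any():
        last = np.max(np.flatnonzero(passing))
        passed = pd.Series(
            [i <= last for i in range(m)], index=order, name="bh_pass"
        )
    else:
        passed = pd.Series(False, index=order, name="bh_pass")
    return pd.DataFrame({"p": p, "bh_threshold": thresh, "bh_pass": passed}).loc[
        p.index
    ]


def selection_report(
    psel: pd.Series,
    pperm: pd.DataFrame,
    config: SelectionConfig,
    fdr_alpha: float | None = None,
) -> pd.DataFrame:
    """Assemble the per-term report: P_sel, permutation p, BH threshold and
    the configured selection flag (p <= p_cut and P_sel > psel_cut)."""
    fdr_alpha = fdr_alpha if fdr_alpha is not None else cfg_alpha(config)
    bh = bh_thresholds(pperm["p_perm"], fdr_alpha)
    rep = pd.DataFrame(
        {
            "p_sel": psel,
            "p_perm": pperm["p_perm"],
            "bh_threshold": bh["bh_threshold"],
            "bh_pass": bh["bh_pass"],
        }
    )
    rep["selected"] = (rep["p_perm"] <= config.p_cut) & (rep["p_sel"] > config.psel_cut)
    return rep.sort_values("p_perm")


def cfg_alpha(config: SelectionConfig) -> float:
    """FDR level paired with a run: 0.05 for main effects, 0.1 for interactions."""
    return 0.1 if config.include_interactions else 0.05
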