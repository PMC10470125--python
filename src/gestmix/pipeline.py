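"""End-to-end orchestration: simulate -> preprocess -> impute -> select ->
effects -> quantile g-computation, under one config and one master seed.

Per-stage seeds are derived deterministically from the master seed, so any
stage is independently rerunnable and two runs with identical config+seed
produce byte-identical output files (wall times go to a separate log).
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cohort import simulate
from .effects import fit_effects, sensitivity_suite, spline_lr
from .mi import impute
from .preprocess import preprocess_table
from .qgc import MixtureSpec, qgcomp_boot, qgcomp_core
from .selection import (
    IMPUTE_COLUMNS,
    SelectionConfig,
    permutation_pvalues,
    selection_report,
    stability_selection,
)
from .specs import (
    METALS,
    OutcomeModelSpec,
    default_outcome,
)

__all__ = ["default_config", "stage_seed", "run_all", "validate_inputs"]

_STAGES = ["simulate", "preprocess", "impute", "select", "effects", "qgcomp"]


def default_config() -> dict:
    """Shipped study-scale configuration; reduce counts for quick runs."""
    return {
        "simulate": {
            "n_cases": 144,
            "n_controls": 1082,
            "n_source": 30000,
            "intercept": -4.2,
            "metal_betas": {"cu": 0.25, "mn": 0.14, "hg": -0.29},
        },
        "preprocess": {"winsorize": True},
        "impute": {"M": 20},
        "select": {
            "B": 200,
            "M": 20,
            "K": 1200,
            "B_perm": 20,
            "M_perm": 10,
            "alpha": 0.9,
            "nlam": 20,
            "nfolds": 5,
            "p_cut": 0.05,
            "psel_cut": 0.6,
            "interactions": False,
        },
        "effects": {"splines": True, "scenarios": []},
        "qgcomp": {
            "q": 4,
            "mixtures": ["MixAll", "MixTox", "MixEssential"],
            "boot": False,
            "n_boot": 200,
            "degree": 2,
        },
    }


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_inputs(
    exposures: pd.DataFrame, qc: pd.DataFrame | None = None
) -> list[dict]:
    """Schema/consistency diagnostics; never mutates the data."""
    diags: list[dict] = []
    for col in ("subject_id", "case", "round"):
        if col not in exposures.columns:
            diags.append({"level": "error", "message": f"missing column {col!r}"})
    metals = [m for m in METALS if m in exposures.columns]
    if not metals:
        diags.append({"level": "error", "message": "no analyte columns found"})
    if "case" in exposures.columns:
        bad = set(exposures["case"].dropna().unique()) - {0, 1}
        if bad:
            diags.append(
                {"level": "error", "message": f"case column has values {sorted(bad)}"}
            )
    for m in metals:
        neg = exposures[m].dropna() <= 0
        if neg.any():
            diags.append(
                {
                    "level": "error",
                    "message": f"nonpositive concentration in column {m!r}",
                }
            )
    if qc is not None and "round" in exposures.columns:
        have = set(zip(qc["metal"], qc["round"]))
        for m in metals:
            for r in exposures.loc[exposures[m].notna(), "round"].unique():
                if (m, r) not in have:
                    diags.append(
                        {
                            "level": "error",
                            "message": f"QC table missing (metal={m}, round={r})",
                        }
                    )
        if (qc["qc_value"] <= 0).any():
            diags.append({"level": "error", "message": "nonpositive QC value"})
    return diags


def run_all(config: dict | None = None, seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Execute every enabled stage and return the machine-readable report.

    When ``outdir`` is given, all stage outputs are written under
    ``outdir/<config-hash>/`` with deterministic formatting.
    """
    cfg = default_config()
    for k, v in (config or {}).items():
        if isinstance(v, dict):
            cfg.setdefault(k, {}).update(v)
        else:
            cfg[k] = v
    chash = gio.config_hash(cfg)
    report: dict = {"config_hash": chash, "seed": int(seed), "warnings": []}
    timings: dict[str, float] = {}
    out = None
    if outdir is not None:
        out = Path(outdir) / chash
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    sim = cfg["simulate"]
    outcome = OutcomeModelSpec(
        intercept=sim.get("intercept", -4.2),
        metal_betas=sim.get("metal_betas", default_outcome().metal_betas),
        covariate_betas=sim.get(
            "covariate_betas", default_outcome().covariate_betas
        ),
        n_cases=sim["n_cases"],
        n_controls=sim["n_controls"],
    )
    cohort = simulate(
        seed=stage_seed(seed, "simulate"),
        outcome_spec=outcome,
        n_source=sim.get("n_source", 30000),
    )
    timings["simulate"] = time.perf_counter() - t0
    if out is not None:
        gio.write_exposures(cohort.observed, out / "exposures.tsv")
        gio.write_qc(cohort.qc, out / "qc.tsv")
        gio.write_json(
            {
                "metal_betas": cohort.metal_betas,
                "covariate_betas": cohort.covariate_betas,
                "seed": cohort.seed,
            },
            out / "truth.json",
        )

    diags = validate_inputs(cohort.observed, cohort.qc)
    if any(d["level"] == "error" for d in diags):
        raise RuntimeError(f"simulated inputs failed validation: {diags}")

    # --- preprocess ----------------------------------------------------
    t0 = time.perf_counter()
    adj = preprocess_table(
        cohort.observed, cohort.qc, do_winsorize=cfg["preprocess"]["winsorize"]
    )
    timings["preprocess"] = time.perf_counter() - t0
    if out is not None:
        gio.write_exposures(adj.df, out / "adjusted.tsv")
        gio.write_json({"stats": adj.stats}, out / "preprocess.json")

    # --- impute --------------------------------------------------------
    t0 = time.perf_counter()
    imp = impute(
        adj.df,
        M=cfg["impute"]["M"],
        bounds=adj.bounds,
        seed=stage_seed(seed, "impute"),
        columns=[c for c in IMPUTE_COLUMNS if c in adj.df.columns],
    )
    timings["impute"] = time.perf_counter() - t0
    if out is not None:
        mdir = out / "imputations"
        for i, d in enumerate(imp.datasets):
            gio.write_table(d, mdir / f"imp_{i:02d}.tsv")
        gio.write_json(
            {"M": imp.M, "seed": imp.seed, "em_iterations": imp.em_iterations},
            mdir / "manifest.json",
        )

    # --- select --------------------------------------------------------
    t0 = time.perf_counter()
    sc = cfg["select"]
    sel_cfg = SelectionConfig(
        B=sc["B"],
        M=sc["M"],
        K=sc["K"],
        B_perm=sc["B_perm"],
        M_perm=sc["M_perm"],
        alpha=sc["alpha"],
        nlam=sc["nlam"],
        nfolds=sc["nfolds"],
        p_cut=sc["p_cut"],
        psel_cut=sc["psel_cut"],
        include_interactions=sc.get("interactions", False),
    )
    psel = stability_selection(
        adj.df, bounds=adj.bounds, config=sel_cfg, seed=stage_seed(seed, "select")
    )
    pperm = permutation_pvalues(
        adj.df,
        psel,
        bounds=adj.bounds,
        config=sel_cfg,
        seed=stage_seed(seed, "select") + 1,
    )
    rep = selection_report(psel, pperm, sel_cfg)
    timings["select"] = time.perf_counter() - t0
    selected = [t for t in rep.index[rep["selected"]] if t in METALS]
    fallback = False
    if len(selected) < 3:
        # follow-up models always examine at least the three strongest
        # candidates, so the effect stage is informative even when the
        # selection rule fires on fewer terms
        ranked = [
            t
            for t in rep.sort_values(["p_perm", "p_sel"], ascending=[True, False]).index
            if t in METALS and t not in selected
        ]
        selected = selected + ranked[: 3 - len(selected)]
        fallback = True
        report["warnings"].append(
            "fewer than 3 exposures met the selection rule; topped up by rank"
        )
    report["selection"] = {
        "selected": selected,
        "fallback_top3": fallback,
        "fit_failures": int(psel.attrs.get("fit_failures", 0)),
        "table": rep.reset_index().rename(columns={"index": "term"}).to_dict("records"),
    }
    if out is not None:
        gio.write_table(rep.reset_index(names="term"), out / "selection.tsv")

    # --- effects -------------------------------------------------------
    t0 = time.perf_counter()
    iqrs = {m: adj.stats[m]["iqr_ln"] for m in selected}
    eff = fit_effects(imp, selected, iqrs=iqrs)
    eff_rows = [
        {
            "exposure": r.exposure,
            "variant": r.variant,
            "or_per_iqr": r.or_per_iqr,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "reliable": r.reliable,
        }
        for r in eff
    ]
    spline_rows = []
    if cfg["effects"].get("splines", True):
        for m in selected:
            spc = spline_lr(imp, m)
            spline_rows.append(
                {
                    "exposure": m,
                    "df": spc.df,
                    "pooled_p": spc.pooled_p,
                    "verdict": spc.verdict,
                }
            )
    sens_df = None
    if cfg["effects"].get("scenarios"):
        sens_df = sensitivity_suite(
            cohort.observed,
            cohort.qc,
            selected,
            scenarios=cfg["effects"]["scenarios"],
            M=max(2, cfg["impute"]["M"] // 4),
            seed=stage_seed(seed, "effects"),
        )
    timings["effects"] = time.perf_counter() - t0
    report["effects"] = eff_rows
    report["splines"] = spline_rows
    if out is not None:
        gio.write_table(pd.DataFrame(eff_rows), out / "effects.tsv")
        if spline_rows:
            gio.write_table(pd.DataFrame(spline_rows), out / "splines.tsv")
        if sens_df is not None:
            gio.write_table(sens_df, out / "sensitivity.tsv")

    # --- qgcomp --------------------------------------------------------
    t0 = time.perf_counter()
    qg = cfg["qgcomp"]
    mix_rows, weight_rows = [], []
    for name in qg["mixtures"]:
        spec = MixtureSpec.named(name, q=qg["q"])
        res = qgcomp_core(imp, spec)
        if qg.get("boot"):
            res = qgcomp_boot(
                imp,
                spec,
                degree=qg.get("degree", 2),
                n_boot=qg.get("n_boot", 200),
                seed=stage_seed(seed, "qgcomp"),
            )
        mix_rows.append(
            {
                "mixture": name,
                "variant": res.variant,
                "or_per_quantile": res.or_per_quantile,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
        for _, w in res.weights.iterrows():
            weight_rows.append(
                {
                    "mixture": name,
                    "member": w["member"],
                    "sign": w["sign"],
                    "weight": w["weight"],
                }
            )
    timings["qgcomp"] = time.perf_counter() - t0
    report["mixtures"] = mix_rows
    report["weights"] = weight_rows
    if out is not None:
        gio.write_table(pd.DataFrame(mix_rows), out / "mixtures.tsv")
        gio.write_table(pd.DataFrame(weight_rows), out / "weights.tsv")
        gio.write_json(report, out / "report.json")
        (out / "run.log").parent.mkdir(exist_ok=True)
        with open(out.parent / "run.log", "a") as fh:
            fh.write(
                " ".join(f"{k}={v:.2f}s" for k, v in timings.items()) + "\n"
            )
    report["_timings"] = timings
    return report
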