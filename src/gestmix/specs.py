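"""Domain types and shipped default configurations.

The defaults describe a nested case-control study of gestational metal and
essential-element exposure: 11 analytes measured in maternal whole blood
(μg/L, except Mg in mg/L), seven adjustment covariates, 144 cases and 1,082
controls drawn from a pregnancy cohort, samples analysed in three analytical
rounds plus a small external-laboratory ("lund") subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats as sps

__all__ = [
    "METALS",
    "TOXIC_METALS",
    "ESSENTIAL_ELEMENTS",
    "ADJUSTMENT_COVARIATES",
    "SpecError",
    "MarginalSpec",
    "CorrelationSpec",
    "CovariateSpec",
    "OutcomeModelSpec",
    "BatchEffectSpec",
    "MissingSpec",
    "default_marginals",
    "default_correlations",
    "default_covariates",
    "default_outcome",
    "default_batch",
    "default_missing",
]

#: Analyte order used everywhere (column order of the exposure table).
METALS = ["hg", "as", "cd", "pb", "mn", "se", "co", "cs", "cu", "zn", "mg"]
TOXIC_METALS = ["as", "hg", "cd", "cs", "pb"]
ESSENTIAL_ELEMENTS = ["mn", "cu", "co", "se", "mg", "zn"]

#: Minimal adjustment set used by every regression model: child sex, birth
#: year period, parity, maternal education, smoking, age at delivery and
#: seafood intake.
ADJUSTMENT_COVARIATES = [
    "sex",
    "birth_period",
    "parity",
    "education",
    "smoking",
    "mat_age",
    "seafood",
]

#: Auxiliary variables that enter the imputation model but not the
#: adjustment set.
AUXILIARY_COVARIATES = ["gest_age", "folate", "bmi"]


class SpecError(ValueError):
    """Raised when a simulation/analysis specification is invalid."""


@dataclass(frozen=True)
class MarginalSpec:
    """Log-normal marginal of one analyte, parameterized by its arithmetic
    mean and SD on the concentration scale.

    ``lod``/``loq`` are optional detection/quantification limits in the same
    units; concentrations below them are left-censored by the generator.
    """

    metal: str
    mean: float
    sd: float
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if not (self.mean > 0):
            raise SpecError(f"{self.metal}: arithmetic mean must be > 0")
        if self.sd < 0:
            raise SpecError(f"{self.metal}: SD must be >= 0")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise SpecError(f"{self.metal}: LOD must not exceed LOQ")


@dataclass(frozen=True)
class CorrelationSpec:
    """Pairwise Spearman correlations between analytes; unlisted pairs are 0."""

    pairs: tuple[tuple[str, str, float], ...] = ()
    on_nonpsd: str = "repair"  # "repair" (nearest-PSD with warning) or "error"

    def __post_init__(self) -> None:
        for a, b, r in self.pairs:
            if a == b:
                raise SpecError(f"self-pair ({a},{b}) not allowed")
            if not -1.0 <= r <= 1.0:
                raise SpecError(f"spearman rho {r} for ({a},{b}) outside [-1,1]")
        if self.on_nonpsd not in ("repair", "error"):
            raise SpecError("on_nonpsd must be 'repair' or 'error'")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distributions of the covariates (independent draws).

    Continuous covariates are normal (truncated at ``lower``); binaries are
    Bernoulli. Probabilities refer to the coded-1 level: sex=1 boy,
    birth_period=1 born in the later period, parity=1 parous, education=1
    high education, smoking=1 any smoking in pregnancy, sga=1 small for
    gestational age.
    """

    continuous: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )  # name -> (mean, sd, lower truncation)
    binary: dict[str, float] = field(default_factory=dict)  # name -> P(=1)

    def __post_init__(self) -> None:
        for name, (m, s, _) in self.continuous.items():
            if s < 0:
                raise SpecError(f"covariate {name}: sd must be >= 0")
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"covariate {name}: probability outside [0,1]")


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Logistic outcome model generating case status.

    Metal betas are log-odds per 1 SD of the ln-concentration; covariate
    betas are per unit (binaries: per level). ``n_cases``/``n_controls`` are
    the exact case-control sample drawn from the source population.
    """

    intercept: float = -4.2
    metal_betas: dict[str, float] = field(default_factory=dict)
    covariate_betas: dict[str, float] = field(default_factory=dict)
    n_cases: int = 144
    n_controls: int = 1082

    def __post_init__(self) -> None:
        for d in (self.metal_betas, self.covariate_betas):
            for k, v in d.items():
                if not math.isfinite(v):
                    raise SpecError(f"beta for {k} must be finite")
        if self.n_cases < 1 or self.n_controls < 1:
            raise SpecError("n_cases and n_controls must be positive")


@dataclass(frozen=True)
class BatchEffectSpec:
    """Multiplicative analytical-round bias plus QC reference replicates.

    ``multipliers`` maps round label -> scalar bias (applied to every
    analyte) or -> {metal: bias}. ``lund_fraction`` of subjects is assigned
    to an extra external-laboratory round labelled ``lund_label``.
    """

    rounds: tuple[str, ...] = ("r1", "r2", "r3")
    proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    multipliers: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: {"r1": 1.0, "r2": 1.1, "r3": 0.9, "lund": 1.05}
    )
    lund_fraction: float = 105 / 1226
    lund_label: str = "lund"
    qc_replicates: int = 5
    qc_noise_cv: float = 0.05
    sample_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if len(self.rounds) != len(self.proportions):
            raise SpecError("rounds and proportions must align")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise SpecError("round proportions must sum to 1")
        if not 0.0 <= self.lund_fraction < 1.0:
            raise SpecError("lund_fraction must be in [0,1)")
        for k in self.all_rounds:
            mult = self.multiplier(k, METALS[0])
            if mult is None:
                raise SpecError(f"round {k}: multiplier missing")
        for k in self.multipliers:
            m = self.multipliers[k]
            vals = m.values() if isinstance(m, dict) else [m]
            if any(v <= 0 for v in vals):
                raise SpecError(f"round {k}: multipliers must be > 0")
        if self.qc_replicates < 1:
            raise SpecError("qc_replicates must be >= 1")

    @property
    def all_rounds(self) -> tuple[str, ...]:
        if self.lund_fraction > 0:
            return self.rounds + (self.lund_label,)
        return self.rounds

    def multiplier(self, round_label: str, metal: str) -> float | None:
        m = self.multipliers.get(round_label)
        if m is None:
            return None
        if isinstance(m, dict):
            return m.get(metal, 1.0)
        return float(m)


@dataclass(frozen=True)
class MissingSpec:
    """Non-censoring missingness: analytes not measured in the external
    round, and MCAR covariate missingness (rates on [0,1])."""

    not_analysed_metals: tuple[str, ...] = ("mg", "cs")
    covariate_mcar: dict[str, float] = field(
        default_factory=lambda: {
            "seafood": 143 / 1226,
            "folate": 273 / 1226,
            "education": 30 / 1226,
            "gest_age": 5 / 1226,
        }
    )

    def __post_init__(self) -> None:
        for name, p in self.covariate_mcar.items():
            if not 0.0 <= p < 1.0:
                raise SpecError(f"MCAR rate for {name} outside [0,1)")


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------

# Arithmetic mean (SD) of the batch-adjusted concentrations in the full
# sample; Mg is only summarized for controls and is used as-is.
_MARGINAL_MOMENTS: dict[str, tuple[float, float]] = {
    "hg": (1.4, 0.9),
    "as": (2.4, 3.0),
    "cd": (0.2, 0.3),
    "pb": (10.0, 5.8),
    "mn": (11.5, 9.4),
    "se": (92.3, 20.2),
    "co": (0.3, 0.9),
    "cs": (2.4, 0.9),
    "cu": (1588.0, 248.0),
    "zn": (5457.0, 1072.0),
    "mg": (30.3, 3.5),
}

# Observed below-limit fractions the default detection limits reproduce:
# As below LOD, Cd and Co below LOQ (counts out of 1,226 subjects).
_CENSOR_FRACTIONS = {"as": 12 / 1226, "cd": 22 / 1226, "co": 33 / 1226}


def _lognorm_quantile(mean: float, sd: float, q: float) -> float:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return math.exp(mu + math.sqrt(sigma2) * sps.norm.ppf(q))


def default_marginals() -> dict[str, MarginalSpec]:
    """Shipped analyte marginals.

    LOD (As) and LOQ (Cd, Co) default to the marginal quantile matching the
    observed below-limit fraction of each analyte; the detection limits
    themselves are laboratory supplement material and not public.
    """
    out: dict[str, MarginalSpec] = {}
    for metal, (mean, sd) in _MARGINAL_MOMENTS.items():
        lod = loq = None
        if metal in _CENSOR_FRACTIONS:
            limit = _lognorm_quantile(mean, sd, _CENSOR_FRACTIONS[metal])
            if metal == "as":
                lod = limit
                loq = 3.0 * limit  # conventional LOQ ~ 3x LOD
            else:
                lod = limit / 3.0
                loq = limit
        out[metal] = MarginalSpec(metal=metal, mean=mean, sd=sd, lod=lod, loq=loq)
    return out


def default_correlations() -> CorrelationSpec:
    """The two strongest reported analyte correlations; others default to 0."""
    return CorrelationSpec(pairs=(("as", "hg", 0.59), ("mg", "zn", 0.53)))


def default_covariates() -> CovariateSpec:
    """Covariate margins of the control (source-population) sample."""
    return CovariateSpec(
        continuous={
            "mat_age": (30.0, 4.5, 15.0),
            "seafood": (36.5, 21.8, 0.0),
            "folate": (511.2, 272.3, 0.0),
            "gest_age": (279.6, 11.7, 150.0),
            "bmi": (23.4, 5.9, 13.0),
        },
        binary={
            "sex": 0.688,
            "birth_period": 0.199,
            "parity": 0.576,
            "education": 0.662,
            "smoking": 0.134,
            "sga": 27 / 1226,
        },
    )


def default_outcome() -> OutcomeModelSpec:
    """Default ground-truth outcome model.

    Metal effects mirror the direction and size of the reported associations
    (Cu and Mn risk-increasing, Hg inverse); covariate effects are
    back-computed from the printed case/control covariate margins.
    """
    return OutcomeModelSpec(
        intercept=-4.2,
        metal_betas={"cu": 0.25, "mn": 0.14, "hg": -0.29},
        covariate_betas={
            "birth_period": 1.59,
            "sex": -0.48,
            "parity": -0.53,
            "smoking": -0.54,
            "seafood": -0.006,
        },
        n_cases=144,
        n_controls=1082,
    )


def default_batch() -> BatchEffectSpec:
    return BatchEffectSpec()


def default_missing() -> MissingSpec:
    return MissingSpec()
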