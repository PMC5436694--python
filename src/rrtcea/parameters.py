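"""Model parameters for the dialysis-policy Markov model.

Every model input is a :class:`ParameterEstimate` — a mean, a standard error
and a distribution family (``beta`` for probabilities and utilities,
``gamma`` for costs, ``fixed`` for quantities held constant).  The full set
of inputs (annual death probabilities, transition probabilities, costs in
2015 IDR, and EQ-5D utilities) lives in :class:`ModelParameters`; the
bundled defaults file reproduces the study values and is loaded with
:func:`default_parameters`.

Distributions are moment-matched: :func:`beta_from_moments` and
:func:`gamma_from_moments` convert a (mean, se) pair into the natural
parameters of the corresponding family, so that probabilistic sensitivity
analysis draws have exactly the stated first two moments.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterEstimate",
    "SurvivalSchedule",
    "ModelParameters",
    "AnalysisSettings",
    "Policy",
    "Perspective",
    "Diagnostic",
    "ParameterError",
    "InfeasibleVarianceError",
    "beta_from_moments",
    "gamma_from_moments",
    "load_parameters",
    "write_parameters",
    "default_parameters",
    "validate_parameter_set",
    "parameters_to_frame",
    "parameters_from_frame",
    "default_wtp_grid",
]


class ParameterError(ValueError):
    """A parameter value or configuration file violates the model contract."""


class InfeasibleVarianceError(ParameterError):
    """The requested (mean, se) pair cannot be matched by a Beta distribution."""


class Policy(str, Enum):
    """Treatment policy arms compared by the evaluation."""

    PD_FIRST = "PD_FIRST"
    HD_FIRST = "HD_FIRST"
    SUPPORTIVE = "SUPPORTIVE"


class Perspective(str, Enum):
    """Costing perspective.

    ``SOCIETAL`` includes direct medical, direct non-medical (travel, food)
    and indirect (caregiver income loss) costs; ``PROVIDER`` includes direct
    medical costs only.
    """

    SOCIETAL = "societal"
    PROVIDER = "provider"


_FAMILIES = ("beta", "gamma", "fixed")


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a given mean and SE.

    Solves ``alpha/(alpha+beta) = mean`` and
    ``var = mean(1-mean)/(alpha+beta+1) = se**2``; feasibility requires
    ``0 < mean < 1`` and ``se**2 < mean(1-mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta moment matching needs mean in (0, 1), got {mean}")
    if se <= 0.0:
        raise ParameterError(f"beta moment matching needs se > 0, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise InfeasibleVarianceError(
            f"se^2 = {var:g} >= mean(1-mean) = {mean * (1 - mean):g}: "
            "no Beta distribution has these moments"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a given mean and SE exactly.

    ``shape = (mean/se)**2`` and ``scale = se**2/mean``.
    """
    if mean <= 0.0:
        raise ParameterError(f"gamma moment matching needs mean > 0, got {mean}")
    if se <= 0.0:
        raise ParameterError(f"gamma moment matching needs se > 0, got {se}")
    return (mean / se) ** 2, se * se / mean


@dataclass(frozen=True)
class ParameterEstimate:
    """One model input: mean, standard error, and sampling family.

    ``se = 0`` (or ``family="fixed"``) marks the parameter as fixed in
    probabilistic sensitivity analysis; deterministic runs always use the
    mean.
    """

    mean: float
    se: float = 0.0
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"unknown distribution family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.se < 0.0:
            raise ParameterError(f"se must be >= 0, got {self.se}")

    @property
    def is_fixed(self) -> bool:
        return self.se == 0.0 or self.family == "fixed"

    def natural_params(self) -> tuple[float, float]:
        """Moment-matched natural parameters of the sampling family."""
        if self.family == "beta":
            return beta_from_moments(self.mean, self.se)
        if self.family == "gamma":
            return gamma_from_moments(self.mean, self.se)
        raise ParameterError("fixed parameters have no sampling distribution")


@dataclass(frozen=True)
class SurvivalSchedule:
    """Annual all-cause death probabilities for dialysis patients.

    The registry follow-up covers years 1..len(annual_death_prob); beyond the
    last observed year the hazard is extrapolated as constant (the final
    year's probability is repeated).  The same schedule is used for both
    modalities: the study found no survival difference between PD and HD.
    """

    annual_death_prob: tuple[ParameterEstimate, ...]

    def __post_init__(self) -> None:
        if len(self.annual_death_prob) < 1:
            raise ParameterError("survival schedule needs at least one year")
        for i, p in enumerate(self.annual_death_prob, start=1):
            if not 0.0 < p.mean < 1.0:
                raise ParameterError(
                    f"survival year {i} death probability must be in (0,1), got {p.mean}"
                )

    def __len__(self) -> int:
        return len(self.annual_death_prob)


# Canonical registry: (field name, kind, units, source).  The order fixes the
# RNG consumption order in PSA sampling and the row order of CSV exports.
PARAMETER_REGISTRY: tuple[tuple[str, str, str, str], ...] = (
    ("p_death_supportive_per_month", "probability", "per month", "expert opinion"),
    ("p_peritonitis_pd", "probability", "per year", "literature"),
    ("p_vascular_complication_hd", "probability", "per year", "renal registry"),
    ("p_switch_hd_to_pd", "probability", "per year", "literature"),
    ("p_switch_pd_to_hd", "probability", "per year", "literature"),
    ("cost_supportive", "cost", "IDR per month", "INA-CBG tariff"),
    ("cost_initial_pd", "cost", "IDR", "hospital billing"),
    ("cost_initial_hd", "cost", "IDR", "hospital billing"),
    ("cost_maintenance_pd_annual", "cost", "IDR per year", "hospital billing"),
    ("cost_maintenance_hd_annual", "cost", "IDR per year", "hospital billing"),
    ("cost_complication_pd_annual", "cost", "IDR per year", "hospital billing"),
    ("cost_complication_hd_annual", "cost", "IDR per year", "hospital billing"),
    ("cost_nonmedical_supportive_lifetime", "cost", "IDR", "questionnaire"),
    ("cost_nonmedical_pd_annual", "cost", "IDR per year", "questionnaire"),
    ("cost_nonmedical_hd_annual", "cost", "IDR per year", "questionnaire"),
    ("cost_indirect_pd_annual", "cost", "IDR per year", "questionnaire"),
    ("cost_indirect_hd_annual", "cost", "IDR per year", "questionnaire"),
    ("utility_pd", "utility", "utility weight", "questionnaire (EQ-5D-3L)"),
    ("utility_hd", "utility", "utility weight", "questionnaire (EQ-5D-3L)"),
    ("utility_pd_complication", "utility", "utility weight", "questionnaire (EQ-5D-3L)"),
    ("utility_hd_complication", "utility", "utility weight", "questionnaire (EQ-5D-3L)"),
)

_PARAM_KIND = {name: kind for name, kind, _, _ in PARAMETER_REGISTRY}


@dataclass(frozen=True)
class ModelParameters:
    """Complete input set for the three-policy dialysis model."""

    survival: SurvivalSchedule
    p_death_supportive_per_month: ParameterEstimate
    p_peritonitis_pd: ParameterEstimate
    p_vascular_complication_hd: ParameterEstimate
    p_switch_hd_to_pd: ParameterEstimate
    p_switch_pd_to_hd: ParameterEstimate
    cost_supportive: ParameterEstimate
    cost_initial_pd: ParameterEstimate
    cost_initial_hd: ParameterEstimate
    cost_maintenance_pd_annual: ParameterEstimate
    cost_maintenance_hd_annual: ParameterEstimate
    cost_complication_pd_annual: ParameterEstimate
    cost_complication_hd_annual: ParameterEstimate
    cost_nonmedical_supportive_lifetime: ParameterEstimate
    cost_nonmedical_pd_annual: ParameterEstimate
    cost_nonmedical_hd_annual: ParameterEstimate
    cost_indirect_pd_annual: ParameterEstimate
    cost_indirect_hd_annual: ParameterEstimate
    utility_pd: ParameterEstimate
    utility_hd: ParameterEstimate
    utility_pd_complication: ParameterEstimate
    utility_hd_complication: ParameterEstimate

    @property
    def utility_supportive(self) -> ParameterEstimate:
        """Utility of supportive care, assumed equal to dialysis with complication (HD)."""
        return self.utility_hd_complication

    def items(self) -> Iterator[tuple[str, ParameterEstimate]]:
        """(name, estimate) pairs in canonical registry order, survival first."""
        for i, p in enumerate(self.survival.annual_death_prob, start=1):
            yield f"survival_year_{i}", p
        for name, _, _, _ in PARAMETER_REGISTRY:
            yield name, getattr(self, name)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: parameter, violated rule, observed value."""

    level: str  # "error" | "warning"
    parameter: str
    rule: str
    observed: float
    message: str


def validate_parameter_set(params: ModelParameters) -> list[Diagnostic]:
    """Check every invariant of the parameter set.

    Returns an empty list when all invariants hold.  A ``warning`` (not an
    error) is emitted when a probability parameter carries a Gamma family, as
    the study's table does for the complication probabilities: draws can then
    exceed 1 and are truncated during sampling.
    """
    out: list[Diagnostic] = []

    def err(name: str, rule: str, obs: float, msg: str) -> None:
        out.append(Diagnostic("error", name, rule, obs, msg))

    for i, p in enumerate(params.survival.annual_death_prob, start=1):
        name = f"survival_year_{i}"
        if not 0.0 < p.mean < 1.0:
            err(name, "probability_in_(0,1)", p.mean, f"{name}: death probability {p.mean}")
        _check_family_feasibility(name, "probability", p, out)

    for name, kind, _, _ in PARAMETER_REGISTRY:
        p: ParameterEstimate = getattr(params, name)
        if kind == "cost":
            if p.mean < 0.0:
                err(name, "cost_nonnegative", p.mean, f"{name}: cost must be >= 0")
        else:
            if not 0.0 <= p.mean <= 1.0:
                err(name, f"{kind}_in_[0,1]", p.mean, f"{name}: {kind} must be in [0, 1]")
        if p.se < 0.0:
            err(name, "se_nonnegative", p.se, f"{name}: se must be >= 0")
        _check_family_feasibility(name, kind, p, out)

    return out


def _check_family_feasibility(
    name: str, kind: str, p: ParameterEstimate, out: list[Diagnostic]
) -> None:
    if p.is_fixed:
        return
    if kind == "probability" and p.family == "gamma":
        out.append(
            Diagnostic(
                "warning",
                name,
                "gamma_family_on_probability",
                p.mean,
                f"{name}: probability parameter sampled from Gamma; draws are truncated to [0, 1]",
            )
        )
    if p.family == "beta":
        if not 0.0 < p.mean < 1.0 or p.se * p.se >= p.mean * (1.0 - p.mean):
            out.append(
                Diagnostic(
                    "error",
                    name,
                    "beta_moments_feasible",
                    p.se,
                    f"{name}: se^2 >= mean(1-mean); Beta moment matching infeasible",
                )
            )
    if p.family == "gamma" and p.mean <= 0.0:
        out.append(
            Diagnostic(
                "error",
                name,
                "gamma_mean_positive",
                p.mean,
                f"{name}: Gamma moment matching needs mean > 0",
            )
        )


# ---------------------------------------------------------------------------
# Serialization

SCHEMA_VERSION = 1


def _estimate_from_mapping(name: str, raw: object) -> ParameterEstimate:
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter {name!r}: expected a mapping, got {type(raw).__name__}")
    if "mean" not in raw:
        raise ParameterError(f"parameter {name!r}: missing required field 'mean'")
    unknown = set(raw) - {"mean", "se", "family"}
    if unknown:
        raise ParameterError(f"parameter {name!r}: unknown fields {sorted(unknown)}")
    try:
        mean = float(raw["mean"])
        se = float(raw.get("se", 0.0))
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"parameter {name!r}: non-numeric mean/se") from exc
    family = str(raw.get("family", "fixed" if se == 0.0 else "beta"))
    try:
        return ParameterEstimate(mean=mean, se=se, family=family)
    except ParameterError as exc:
        raise ParameterError(f"parameter {name!r}: {exc}") from exc


def parameters_from_dict(doc: dict) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a parsed config mapping."""
    if not isinstance(doc, dict):
        raise ParameterError("config root must be a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ParameterError(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")
    surv_raw = doc.get("survival")
    if not isinstance(surv_raw, dict) or "annual_death_prob" not in surv_raw:
        raise ParameterError("missing 'survival.annual_death_prob' section")
    schedule = SurvivalSchedule(
        tuple(
            _estimate_from_mapping(f"survival_year_{i}", row)
            for i, row in enumerate(surv_raw["annual_death_prob"], start=1)
        )
    )
    block = doc.get("parameters")
    if not isinstance(block, dict):
        raise ParameterError("missing 'parameters' section")
    kwargs: dict[str, ParameterEstimate] = {}
    for name, _, _, _ in PARAMETER_REGISTRY:
        if name not in block:
            raise ParameterError(f"missing required parameter {name!r}")
        kwargs[name] = _estimate_from_mapping(name, block[name])
    unknown = set(block) - set(kwargs)
    if unknown:
        raise ParameterError(f"unknown parameters in config: {sorted(unknown)}")
    params = ModelParameters(survival=schedule, **kwargs)
    errors = [d for d in validate_parameter_set(params) if d.level == "error"]
    if errors:
        raise ParameterError(
            "invalid parameter set: " + "; ".join(d.message for d in errors)
        )
    return params


def parameters_to_dict(params: ModelParameters) -> dict:
    def enc(p: ParameterEstimate) -> dict:
        return {"mean": p.mean, "se": p.se, "family": p.family}

    return {
        "schema_version": SCHEMA_VERSION,
        "survival": {"annual_death_prob": [enc(p) for p in params.survival.annual_death_prob]},
        "parameters": {name: enc(getattr(params, name)) for name, _, _, _ in PARAMETER_REGISTRY},
    }


def load_parameters(path) -> ModelParameters:
    """Load and validate a parameter config (YAML) from ``path``."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ParameterError(f"config not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ParameterError(f"config {path} is not valid YAML: {exc}") from exc
    return parameters_from_dict(doc)


def write_parameters(params: ModelParameters, path) -> None:
    """Write a parameter set as YAML; round-trips with :func:`load_parameters`."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """The bundled default parameter set (the study's input table)."""
    ref = importlib.resources.files("rrtcea").joinpath("data/table1_defaults.yaml")
    return parameters_from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def parameters_to_frame(params: ModelParameters) -> pd.DataFrame:
    """Tabular export: columns name, mean, se, family, units, source."""
    meta = {name: (units, source) for name, _, units, source in PARAMETER_REGISTRY}
    rows = []
    for name, p in params.items():
        units, source = meta.get(name, ("per year", "renal registry"))
        rows.append(
            {"name": name, "mean": p.mean, "se": p.se, "family": p.family,
             "units": units, "source": source}
        )
    return pd.DataFrame(rows)


def parameters_from_frame(df: pd.DataFrame) -> ModelParameters:
    """Inverse of :func:`parameters_to_frame` (units/source columns are ignored)."""
    required = {"name", "mean", "se", "family"}
    if not required.issubset(df.columns):
        raise ParameterError(f"parameter table needs columns {sorted(required)}")
    by_name = {
        str(r["name"]): {"mean": r["mean"], "se": r["se"], "family": r["family"]}
        for _, r in df.iterrows()
    }
    surv_rows = []
    i = 1
    while f"survival_year_{i}" in by_name:
        surv_rows.append(by_name.pop(f"survival_year_{i}"))
        i += 1
    doc = {
        "schema_version": SCHEMA_VERSION,
        "survival": {"annual_death_prob": surv_rows},
        "parameters": by_name,
    }
    return parameters_from_dict(doc)


# ---------------------------------------------------------------------------
# Analysis settings


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid: 0 to 400 million IDR/QALY in 2-million steps."""
    return np.arange(0.0, 400e6 + 1.0, 2e6)


@dataclass(frozen=True)
class AnalysisSettings:
    """Run configuration: policy, perspective, discounting, horizon, PSA size.

    ``horizon_years = 22`` operationalizes the lifetime horizon: residual
    cohort survival is below 4% by then under constant-hazard extrapolation.
    ``complication_months`` is the in-year duration of a complication
    sub-state episode.
    """

    policy: Policy = Policy.PD_FIRST
    perspective: Perspective = Perspective.SOCIETAL
    discount_rate: float = 0.03
    horizon_years: int = 22
    complication_months: int = 1
    apply_initiation_cost_on_switch: bool = True
    half_cycle_correction: bool = False
    wtp_grid: tuple[float, ...] = field(default_factory=lambda: tuple(default_wtp_grid()))
    psa_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discount_rate < 0.0:
            raise ParameterError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.horizon_years < 1:
            raise ParameterError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if not 1 <= self.complication_months <= 12:
            raise ParameterError(
                f"complication_months must be in 1..12, got {self.complication_months}"
            )
        if self.psa_draws < 1:
            raise ParameterError(f"psa_draws must be >= 1, got {self.psa_draws}")
        grid = np.asarray(self.wtp_grid, dtype=float)
        if grid.size and (np.any(grid < 0.0) or np.any(np.diff(grid) <= 0.0)):
            raise ParameterError("wtp_grid must be non-negative and strictly increasing")

    def replace(self, **changes) -> "AnalysisSettings":
        return dataclasses.replace(self, **changes)
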