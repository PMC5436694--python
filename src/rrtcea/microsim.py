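"""Patient-level simulation: validation oracle and synthetic survey data.

The microsimulation draws individual trajectories with exactly the cohort
engine's per-cycle probabilities and event ordering (switch at cycle start,
then the year's costs, then death, with survivors accruing outcomes at cycle
end), so its sample means converge to the cohort model's expectations.  It
exists to validate the cohort engine, not to replace it.

:func:`generate_synthetic_survey` emulates the study's patient
questionnaire: per-patient household costs, income loss and EQ-5D utilities
drawn from the moment-matched input distributions, using the published
standard errors as the patient-level spread (the study does not report
patient-level standard deviations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import effective_death_prob
from .outcomes import discount_factor
from .parameters import (
    AnalysisSettings,
    ModelParameters,
    ParameterError,
    ParameterEstimate,
    Policy,
)

__all__ = [
    "PatientTrajectory",
    "MicrosimResult",
    "simulate_patient",
    "run_microsim",
    "generate_synthetic_survey",
    "estimate_survey_parameters",
]


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated patient: time-stamped events plus lifetime accruals.

    Events are ``(time_months, kind, detail)`` with kinds ``entry``,
    ``switch``, ``complication`` and ``death``; costs are discounted at the
    settings rate.
    """

    policy: Policy
    events: tuple[tuple[float, str, str], ...]
    ly: float
    qaly: float
    qaly_discounted: float
    cost_discounted_societal: float
    cost_discounted_provider: float

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.events]
        if times != sorted(times):
            raise ParameterError("trajectory events must be time-ordered")
        deaths = [t for t, kind, _ in self.events if kind == "death"]
        if len(deaths) > 1:
            raise ParameterError("at most one death per trajectory")
        if deaths and any(t > deaths[0] for t, _, _ in self.events):
            raise ParameterError("no events after death")

    @property
    def death_time_months(self) -> float | None:
        for t, kind, _ in self.events:
            if kind == "death":
                return t
        return None


def simulate_patient(
    params: ModelParameters,
    policy: Policy,
    rng: np.random.Generator,
    settings: AnalysisSettings | None = None,
) -> PatientTrajectory:
    """Sample one trajectory; reproducible from the generator state."""
    settings = settings or AnalysisSettings(policy=policy)
    if policy is Policy.SUPPORTIVE:
        return _simulate_supportive(params, rng, settings)
    return _simulate_dialysis(params, policy, rng, settings)


def _simulate_supportive(
    params: ModelParameters, rng: np.random.Generator, settings: AnalysisSettings
) -> PatientTrajectory:
    p = params.p_death_supportive_per_month.mean
    u = params.utility_supportive.mean
    r = settings.discount_rate
    events: list[tuple[float, str, str]] = [(0.0, "entry", "SUPPORTIVE")]
    c_soc = params.cost_nonmedical_supportive_lifetime.mean
    c_prov = 0.0
    ly = qaly = qaly_d = 0.0
    for m in range(1, settings.horizon_years * 12 + 1):
        cost = params.cost_supportive.mean * discount_factor(r, (m - 1) / 12.0)
        c_soc += cost
        c_prov += cost
        ly += 1.0 / 12.0
        qaly += u / 12.0
        qaly_d += u / 12.0 * discount_factor(r, m / 12.0)
        if rng.random() < p:
            events.append((float(m), "death", "SUPPORTIVE"))
            break
    return PatientTrajectory(
        policy=Policy.SUPPORTIVE,
        events=tuple(events),
        ly=ly,
        qaly=qaly,
        qaly_discounted=qaly_d,
        cost_discounted_societal=c_soc,
        cost_discounted_provider=c_prov,
    )


def _simulate_dialysis(
    params: ModelParameters,
    policy: Policy,
    rng: np.random.Generator,
    settings: AnalysisSettings,
) -> PatientTrajectory:
    r = settings.discount_rate
    frac = settings.complication_months / 12.0
    on_pd = policy is Policy.PD_FIRST
    events: list[tuple[float, str, str]] = [(0.0, "entry", "PD" if on_pd else "HD")]
    init = {True: params.cost_initial_pd.mean, False: params.cost_initial_hd.mean}
    c_prov = init[on_pd]
    c_soc = init[on_pd]
    ly = qaly = qaly_d = 0.0
    for t in range(1, settings.horizon_years + 1):
        d0 = discount_factor(r, float(t - 1))
        d1 = discount_factor(r, float(t))
        month0 = float((t - 1) * 12)
        p_switch = params.p_switch_pd_to_hd.mean if on_pd else params.p_switch_hd_to_pd.mean
        if rng.random() < p_switch:
            on_pd = not on_pd
            if settings.apply_initiation_cost_on_switch:
                c_prov += init[on_pd] * d0
                c_soc += init[on_pd] * d0
            events.append((month0, "switch", "PD" if on_pd else "HD"))
        maint = (
            params.cost_maintenance_pd_annual.mean if on_pd
            else params.cost_maintenance_hd_annual.mean
        )
        nonmed = (
            params.cost_nonmedical_pd_annual.mean if on_pd
            else params.cost_nonmedical_hd_annual.mean
        )
        indirect = (
            params.cost_indirect_pd_annual.mean if on_pd
            else params.cost_indirect_hd_annual.mean
        )
        c_prov += maint * d0
        c_soc += (maint + nonmed + indirect) * d0
        p_comp = (
            params.p_peritonitis_pd.mean if on_pd else params.p_vascular_complication_hd.mean
        )
        had_comp = rng.random() < min(p_comp, 1.0)
        if had_comp:
            c_comp = (
                params.cost_complication_pd_annual.mean if on_pd
                else params.cost_complication_hd_annual.mean
            )
            c_prov += c_comp * d0
            c_soc += c_comp * d0
            events.append((month0, "complication", "PD" if on_pd else "HD"))
        if rng.random() < effective_death_prob(params.survival, t):
            events.append((float(t * 12), "death", "PD" if on_pd else "HD"))
            break
        u_base = params.utility_pd.mean if on_pd else params.utility_hd.mean
        u_comp = (
            params.utility_pd_complication.mean if on_pd
            else params.utility_hd_complication.mean
        )
        u_year = frac * u_comp + (1.0 - frac) * u_base if had_comp else u_base
        ly += 1.0
        qaly += u_year
        qaly_d += u_year * d1
    return PatientTrajectory(
        policy=policy,
        events=tuple(events),
        ly=ly,
        qaly=qaly,
        qaly_discounted=qaly_d,
        cost_discounted_societal=c_soc,
        cost_discounted_provider=c_prov,
    )


_QUANTITIES = (
    "ly_undiscounted",
    "qaly_undiscounted",
    "qaly_discounted",
    "cost_discounted_societal",
    "cost_discounted_provider",
    "cost_direct_medical",
    "cost_direct_nonmedical",
    "cost_indirect",
)


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimates (mean and standard error) of the cohort quantities."""

    policy: Policy
    n_patients: int
    seed: int
    summary: pd.DataFrame  # index: quantity; columns: mean, se

    def mean(self, quantity: str) -> float:
        return float(self.summary.loc[quantity, "mean"])

    def se(self, quantity: str) -> float:
        return float(self.summary.loc[quantity, "se"])


def run_microsim(
    params: ModelParameters,
    settings: AnalysisSettings,
    n_patients: int,
    seed: int,
) -> MicrosimResult:
    """Vectorized patient-level run; averages match ``accrue_outcomes`` conventions."""
    if n_patients < 1:
        raise ParameterError(f"n_patients must be >= 1, got {n_patients}")
    rng = np.random.default_rng(seed)
    if settings.policy is Policy.SUPPORTIVE:
        cols = _microsim_supportive(params, settings, n_patients, rng)
    else:
        cols = _microsim_dialysis(params, settings, n_patients, rng)
    rows = {}
    for name in _QUANTITIES:
        x = cols[name]
        rows[name] = {
            "mean": float(x.mean()),
            "se": float(x.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else np.inf,
        }
    return MicrosimResult(
        policy=settings.policy,
        n_patients=n_patients,
        seed=seed,
        summary=pd.DataFrame.from_dict(rows, orient="index"),
    )


def _microsim_dialysis(params, settings, n, rng) -> dict[str, np.ndarray]:
    r = settings.discount_rate
    frac = settings.complication_months / 12.0
    p_pd2hd = params.p_switch_pd_to_hd.mean
    p_hd2pd = params.p_switch_hd_to_pd.mean
    p_perit = min(params.p_peritonitis_pd.mean, 1.0)
    p_vasc = min(params.p_vascular_complication_hd.mean, 1.0)
    init_pd, init_hd = params.cost_initial_pd.mean, params.cost_initial_hd.mean

    alive = np.ones(n, dtype=bool)
    on_pd = np.full(n, settings.policy is Policy.PD_FIRST)
    ly = np.zeros(n)
    qaly_u = np.zeros(n)
    qaly_d = np.zeros(n)
    c_dm = np.full(n, init_pd if settings.policy is Policy.PD_FIRST else init_hd)
    c_dnm = np.zeros(n)
    c_ind = np.zeros(n)

    for t in range(1, settings.horizon_years + 1):
        d0 = discount_factor(r, float(t - 1))
        d1 = discount_factor(r, float(t))
        switching = alive & (rng.random(n) < np.where(on_pd, p_pd2hd, p_hd2pd))
        if settings.apply_initiation_cost_on_switch:
            c_dm += switching * np.where(on_pd, init_hd, init_pd) * d0
        on_pd = on_pd ^ switching
        comp = alive & (rng.random(n) < np.where(on_pd, p_perit, p_vasc))
        maint = np.where(
            on_pd,
            params.cost_maintenance_pd_annual.mean,
            params.cost_maintenance_hd_annual.mean,
        )
        c_comp = np.where(
            on_pd,
            params.cost_complication_pd_annual.mean,
            params.cost_complication_hd_annual.mean,
        )
        c_dm += (alive * maint + comp * c_comp) * d0
        c_dnm += alive * np.where(
            on_pd,
            params.cost_nonmedical_pd_annual.mean,
            params.cost_nonmedical_hd_annual.mean,
        ) * d0
        c_ind += alive * np.where(
            on_pd,
            params.cost_indirect_pd_annual.mean,
            params.cost_indirect_hd_annual.mean,
        ) * d0
        died = alive & (rng.random(n) < effective_death_prob(params.survival, t))
        alive &= ~died
        u_base = np.where(on_pd, params.utility_pd.mean, params.utility_hd.mean)
        u_comp = np.where(
            on_pd, params.utility_pd_complication.mean, params.utility_hd_complication.mean
        )
        u_year = np.where(comp, frac * u_comp + (1.0 - frac) * u_base, u_base)
        ly += alive
        qaly_u += alive * u_year
        qaly_d += alive * u_year * d1

    return {
        "ly_undiscounted": ly,
        "qaly_undiscounted": qaly_u,
        "qaly_discounted": qaly_d,
        "cost_discounted_societal": c_dm + c_dnm + c_ind,
        "cost_discounted_provider": c_dm,
        "cost_direct_medical": c_dm,
        "cost_direct_nonmedical": c_dnm,
        "cost_indirect": c_ind,
    }


def _microsim_supportive(params, settings, n, rng) -> dict[str, np.ndarray]:
    p = params.p_death_supportive_per_month.mean
    u = params.utility_supportive.mean
    r = settings.discount_rate
    cap = settings.horizon_years * 12
    k = np.minimum(rng.geometric(p, size=n), cap).astype(float)  # lived months
    x = (1.0 + r) ** (-1.0 / 12.0)
    if r > 0.0:
        sum_end = x * (1.0 - x**k) / (1.0 - x)       # sum of x^m, m = 1..k
        sum_start = (1.0 - x**k) / (1.0 - x)          # sum of x^(m-1)
    else:
        sum_end = sum_start = k
    ly = k / 12.0
    c_dm = params.cost_supportive.mean * sum_start
    c_dnm = np.full(n, params.cost_nonmedical_supportive_lifetime.mean)
    return {
        "ly_undiscounted": ly,
        "qaly_undiscounted": ly * u,
        "qaly_discounted": u / 12.0 * sum_end,
        "cost_discounted_societal": c_dm + c_dnm,
        "cost_discounted_provider": c_dm,
        "cost_direct_medical": c_dm,
        "cost_direct_nonmedical": c_dnm,
        "cost_indirect": np.zeros(n),
    }


# ---------------------------------------------------------------------------
# Synthetic questionnaire data

_SURVEY_FIELDS = {
    "PD": {
        "annual_direct_nonmedical_cost": "cost_nonmedical_pd_annual",
        "annual_indirect_cost": "cost_indirect_pd_annual",
        "utility_no_complication": "utility_pd",
        "utility_complication": "utility_pd_complication",
    },
    "HD": {
        "annual_direct_nonmedical_cost": "cost_nonmedical_hd_annual",
        "annual_indirect_cost": "cost_indirect_hd_annual",
        "utility_no_complication": "utility_hd",
        "utility_complication": "utility_hd_complication",
    },
}


def generate_synthetic_survey(
    params: ModelParameters, n: int, seed: int
) -> pd.DataFrame:
    """Synthetic patient questionnaire with ``n`` patients per modality arm.

    Per-patient values are drawn from each parameter's moment-matched family
    using the published standard error as the patient-level spread, so large
    samples reproduce the published means and SEs under re-estimation.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for modality in ("PD", "HD"):
        for _ in range(n):
            pid += 1
            row = {"patient_id": pid, "modality": modality}
            for col, pname in _SURVEY_FIELDS[modality].items():
                est: ParameterEstimate = getattr(params, pname)
                row[col] = _survey_draw(est, rng)
            rows.append(row)
    return pd.DataFrame(rows)


def _survey_draw(est: ParameterEstimate, rng: np.random.Generator) -> float:
    if est.is_fixed:
        return est.mean
    if est.family == "beta":
        a, b = est.natural_params()
        return float(rng.beta(a, b))
    shape, scale = est.natural_params()
    return float(rng.gamma(shape, scale))


def estimate_survey_parameters(survey: pd.DataFrame) -> dict[str, ParameterEstimate]:
    """Refit (mean, spread) estimates from a synthetic survey.

    Inverse of :func:`generate_synthetic_survey` in the large-sample limit:
    the sample mean estimates the published mean and the sample standard
    deviation the published SE.
    """
    out = {}
    for modality, fields in _SURVEY_FIELDS.items():
        sub = survey[survey["modality"] == modality]
        for col, pname in fields.items():
            x = sub[col].to_numpy(dtype=float)
            family = "beta" if col.startswith("utility") else "gamma"
            out[pname] = ParameterEstimate(
                mean=float(x.mean()),
                se=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                family=family,
            )
    return out
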