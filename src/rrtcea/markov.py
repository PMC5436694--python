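"""Deterministic cohort state-transition engine.

The model tracks a cohort of incident ESRD patients through the states
PD, PD with complication (peritonitis), HD, HD with complication (vascular
access), supportive care, and death.  Dialysis arms use annual cycles;
supportive care uses monthly cycles.  Complication states are within-cycle
sub-states: a patient who develops a complication spends
``complication_months`` of that year in the sub-state (reduced utility,
extra treatment cost) and returns to the uncomplicated state of the current
modality.

Within-cycle conventions (fixed, and shared exactly with the patient-level
microsimulation in :mod:`rrtcea.microsim`):

1. at cycle start, living patients may switch modality (annual probability);
   switchers are charged the new modality's initiation cost at that moment;
2. the year's treatment costs (maintenance, expected complication treatment,
   and — societal perspective — household and indirect costs) are charged to
   everyone entering the year, at cycle start;
3. deaths occur during the cycle (annual probability from the survival
   schedule, identical in every living dialysis state);
4. survivors accrue the cycle's life-years and utility at cycle end.

The supportive-care arm instead counts the month of death as lived, so its
life expectancy is the full geometric mean 1/p months.  Both conventions are
deliberate model calibration choices; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .parameters import (
    AnalysisSettings,
    ModelParameters,
    ParameterError,
    Policy,
    SurvivalSchedule,
)

__all__ = [
    "HealthState",
    "CohortTrace",
    "effective_death_prob",
    "cumulative_survival",
    "run_dialysis_trace",
    "run_supportive_trace",
    "run_trace",
]

_CONSERVATION_TOL = 1e-9
_RESIDUAL_TOL = 1e-9


class HealthState(str, Enum):
    PD = "PD"
    PD_COMPLICATION = "PD_COMPLICATION"
    HD = "HD"
    HD_COMPLICATION = "HD_COMPLICATION"
    SUPPORTIVE = "SUPPORTIVE"
    DEAD = "DEAD"


STATES: tuple[HealthState, ...] = tuple(HealthState)
_IDX = {s: i for i, s in enumerate(STATES)}


def effective_death_prob(survival: SurvivalSchedule, year: int) -> float:
    """Annual death probability in dialysis arms for a given 1-based year.

    Years beyond the observed schedule repeat the final year's value
    (constant-hazard extrapolation).  Identical for PD and HD.
    """
    if year < 1:
        raise ParameterError(f"year must be >= 1, got {year}")
    sched = survival.annual_death_prob
    return sched[min(year, len(sched)) - 1].mean


def cumulative_survival(survival: SurvivalSchedule, year: int) -> float:
    """Probability of being alive at the end of ``year`` (year 0 -> 1.0)."""
    if year < 0:
        raise ParameterError(f"year must be >= 0, got {year}")
    out = 1.0
    for t in range(1, year + 1):
        out *= 1.0 - effective_death_prob(survival, t)
    return out


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of one policy's cohort run.

    ``occupancy`` holds end-of-cycle state fractions (rows sum to 1).
    ``ly``/``qaly`` are the cycle's undiscounted accruals, dated
    ``outcome_times`` (years); the three cost streams are undiscounted
    accruals dated ``cost_times``.  Discounting and aggregation happen in
    :func:`rrtcea.outcomes.accrue_outcomes`.
    """

    policy: Policy
    cycle_length_years: float
    occupancy: np.ndarray          # (n_cycles, 6), column order = STATES
    outcome_times: np.ndarray      # (n_cycles,) end-of-cycle times, years
    cost_times: np.ndarray         # (n_cycles,) start-of-cycle times, years
    ly: np.ndarray
    qaly: np.ndarray
    cost_direct_medical: np.ndarray
    cost_direct_nonmedical: np.ndarray
    cost_indirect: np.ndarray

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _CONSERVATION_TOL):
            worst = int(np.argmax(np.abs(sums - 1.0)))
            raise ParameterError(
                f"occupancy conservation violated at cycle {worst}: sum = {sums[worst]!r}"
            )
        dead = self.occupancy[:, _IDX[HealthState.DEAD]]
        if np.any(np.diff(dead) < -_CONSERVATION_TOL):
            raise ParameterError("DEAD occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def living(self) -> np.ndarray:
        """End-of-cycle living fraction per cycle."""
        return 1.0 - self.occupancy[:, _IDX[HealthState.DEAD]]

    def state_occupancy(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, _IDX[state]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export (one row per cycle x state)."""
        rows = []
        for i in range(self.n_cycles):
            for s in STATES:
                rows.append(
                    {
                        "cycle_index": i + 1,
                        "time_years": self.outcome_times[i],
                        "state": s.value,
                        "occupancy": self.occupancy[i, _IDX[s]],
                        "ly": self.ly[i] if s is not HealthState.DEAD else 0.0,
                        "qaly": self.qaly[i] if s is not HealthState.DEAD else 0.0,
                        "cost_direct_medical": self.cost_direct_medical[i],
                        "cost_direct_nonmedical": self.cost_direct_nonmedical[i],
                        "cost_indirect": self.cost_indirect[i],
                    }
                )
        return pd.DataFrame(rows)


def _complication_weighted_utility(
    u_base: float, u_comp: float, p_comp: float, complication_months: int
) -> float:
    """Expected annual utility weight folding the in-year complication episode."""
    frac = complication_months / 12.0
    return (1.0 - p_comp) * u_base + p_comp * (frac * u_comp + (1.0 - frac) * u_base)


def run_dialysis_trace(params: ModelParameters, settings: AnalysisSettings) -> CohortTrace:
    """Run the annual-cycle cohort model for a dialysis-first policy."""
    if settings.policy not in (Policy.PD_FIRST, Policy.HD_FIRST):
        raise ParameterError(f"run_dialysis_trace needs a dialysis policy, got {settings.policy}")
    H = settings.horizon_years
    p_pd2hd = params.p_switch_pd_to_hd.mean
    p_hd2pd = params.p_switch_hd_to_pd.mean
    p_perit = min(params.p_peritonitis_pd.mean, 1.0)
    p_vasc = min(params.p_vascular_complication_hd.mean, 1.0)
    cm = settings.complication_months
    u_pd = _complication_weighted_utility(
        params.utility_pd.mean, params.utility_pd_complication.mean, p_perit, cm
    )
    u_hd = _complication_weighted_utility(
        params.utility_hd.mean, params.utility_hd_complication.mean, p_vasc, cm
    )
    c_med_pd = params.cost_maintenance_pd_annual.mean + p_perit * params.cost_complication_pd_annual.mean
    c_med_hd = params.cost_maintenance_hd_annual.mean + p_vasc * params.cost_complication_hd_annual.mean
    c_nonmed_pd = params.cost_nonmedical_pd_annual.mean
    c_nonmed_hd = params.cost_nonmedical_hd_annual.mean
    c_ind_pd = params.cost_indirect_pd_annual.mean
    c_ind_hd = params.cost_indirect_hd_annual.mean
    init_pd = params.cost_initial_pd.mean
    init_hd = params.cost_initial_hd.mean

    occ = np.zeros((H, len(STATES)))
    ly = np.zeros(H)
    qaly = np.zeros(H)
    c_dm = np.zeros(H)
    c_dnm = np.zeros(H)
    c_ind = np.zeros(H)

    S = 1.0                                       # living fraction at cycle start
    f = 1.0 if settings.policy is Policy.PD_FIRST else 0.0  # PD share of the living
    # entry initiation at time 0 (cycle-start charge of cycle 1)
    c_dm[0] += init_pd if settings.policy is Policy.PD_FIRST else init_hd

    for t in range(1, H + 1):
        i = t - 1
        # 1. switching at cycle start; switchers pay the new modality's initiation
        if settings.apply_initiation_cost_on_switch:
            c_dm[i] += S * (f * p_pd2hd * init_hd + (1.0 - f) * p_hd2pd * init_pd)
        f = f * (1.0 - p_pd2hd) + (1.0 - f) * p_hd2pd
        # 2. year-t treatment costs for everyone entering the year
        c_dm[i] += S * (f * c_med_pd + (1.0 - f) * c_med_hd)
        c_dnm[i] += S * (f * c_nonmed_pd + (1.0 - f) * c_nonmed_hd)
        c_ind[i] += S * (f * c_ind_pd + (1.0 - f) * c_ind_hd)
        # 3. deaths during the year
        S_start = S
        S = S * (1.0 - effective_death_prob(params.survival, t))
        # 4. survivors accrue the year's outcomes
        if settings.half_cycle_correction:
            lived = 0.5 * (S_start + S)
        else:
            lived = S
        ly[i] = lived
        qaly[i] = lived * (f * u_pd + (1.0 - f) * u_hd)
        # end-of-cycle occupancy, complication sub-states shown explicitly
        occ[i, _IDX[HealthState.PD]] = S * f * (1.0 - p_perit)
        occ[i, _IDX[HealthState.PD_COMPLICATION]] = S * f * p_perit
        occ[i, _IDX[HealthState.HD]] = S * (1.0 - f) * (1.0 - p_vasc)
        occ[i, _IDX[HealthState.HD_COMPLICATION]] = S * (1.0 - f) * p_vasc
        occ[i, _IDX[HealthState.DEAD]] = 1.0 - S

    times = np.arange(1, H + 1, dtype=float)
    offset = 0.5 if settings.half_cycle_correction else 0.0
    return CohortTrace(
        policy=settings.policy,
        cycle_length_years=1.0,
        occupancy=occ,
        outcome_times=times - offset,
        cost_times=times - 1.0,
        ly=ly,
        qaly=qaly,
        cost_direct_medical=c_dm,
        cost_direct_nonmedical=c_dnm,
        cost_indirect=c_ind,
    )


def run_supportive_trace(params: ModelParameters, settings: AnalysisSettings) -> CohortTrace:
    """Run the monthly-cycle supportive-care arm.

    Runs until residual living occupancy falls below 1e-9 or the horizon is
    reached.  Patients alive at the start of a month live (and are costed
    for) that month even if they die in it, so undiscounted life expectancy
    equals the geometric mean 1/p months.
    """
    p = params.p_death_supportive_per_month.mean
    if not 0.0 < p <= 1.0:
        raise ParameterError(f"supportive death probability must be in (0, 1], got {p}")
    u = params.utility_supportive.mean
    c_month = params.cost_supportive.mean
    max_cycles = settings.horizon_years * 12

    occ_rows, ly, qaly, c_dm, c_dnm = [], [], [], [], []
    alive = 1.0
    m = 0
    while alive > _RESIDUAL_TOL and m < max_cycles:
        ly.append(alive / 12.0)
        qaly.append(alive / 12.0 * u)
        c_dm.append(alive * c_month)
        c_dnm.append(params.cost_nonmedical_supportive_lifetime.mean if m == 0 else 0.0)
        alive *= 1.0 - p
        row = np.zeros(len(STATES))
        row[_IDX[HealthState.SUPPORTIVE]] = alive
        row[_IDX[HealthState.DEAD]] = 1.0 - alive
        occ_rows.append(row)
        m += 1

    n = len(occ_rows)
    months = np.arange(1, n + 1, dtype=float)
    return CohortTrace(
        policy=Policy.SUPPORTIVE,
        cycle_length_years=1.0 / 12.0,
        occupancy=np.vstack(occ_rows),
        outcome_times=months / 12.0,
        cost_times=(months - 1.0) / 12.0,
        ly=np.asarray(ly),
        qaly=np.asarray(qaly),
        cost_direct_medical=np.asarray(c_dm),
        cost_direct_nonmedical=np.asarray(c_dnm),
        cost_indirect=np.zeros(n),
    )


def run_trace(params: ModelParameters, settings: AnalysisSettings) -> CohortTrace:
    """Dispatch to the dialysis or supportive engine by ``settings.policy``."""
    if settings.policy is Policy.SUPPORTIVE:
        return run_supportive_trace(params, settings)
    return run_dialysis_trace(params, settings)
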