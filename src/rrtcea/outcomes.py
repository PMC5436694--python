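"""Lifetime outcomes, discounting, ICERs, and the cost-effectiveness frontier.

Headline life-years and QALYs are reported undiscounted (as in the study's
results); incremental cost-effectiveness ratios always use discounted costs
and discounted QALYs.  Both variants are computed for every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .markov import CohortTrace
from .parameters import AnalysisSettings, ModelParameters, ParameterError, Perspective, Policy

__all__ = [
    "PolicyOutcome",
    "CEAResult",
    "discount_factor",
    "accrue_outcomes",
    "icer",
    "net_monetary_benefit",
    "frontier",
    "DOMINATED",
    "DOMINANT",
    "EQUIVALENT",
]

DOMINATED = "dominated"
DOMINANT = "dominant"
EQUIVALENT = "equivalent"

ICERValue = Union[float, str]


def discount_factor(rate: float, time_years) -> np.ndarray | float:
    """Present-value factor ``(1 + rate) ** -t`` for time in years."""
    t = np.asarray(time_years, dtype=float)
    if rate < 0.0:
        raise ParameterError(f"discount rate must be >= 0, got {rate}")
    if np.any(t < 0.0):
        raise ParameterError("time must be >= 0")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PolicyOutcome:
    """Lifetime per-patient results for one policy under one settings object.

    Costs are IDR; component fields are discounted.  The *active*
    perspective (``perspective``) selects which total
    :attr:`cost_discounted` and :func:`net_monetary_benefit` use.
    """

    policy: Policy
    perspective: Perspective
    discount_rate: float
    ly_undiscounted: float
    qaly_undiscounted: float
    qaly_discounted: float
    cost_direct_medical: float
    cost_direct_nonmedical: float
    cost_indirect: float
    cost_undiscounted_societal: float
    cost_undiscounted_provider: float

    @property
    def cost_discounted_provider(self) -> float:
        return self.cost_direct_medical

    @property
    def cost_discounted_societal(self) -> float:
        return self.cost_direct_medical + self.cost_direct_nonmedical + self.cost_indirect

    @property
    def cost_discounted(self) -> float:
        if self.perspective is Perspective.PROVIDER:
            return self.cost_discounted_provider
        return self.cost_discounted_societal

    def as_dict(self) -> dict:
        return {
            "policy": self.policy.value,
            "perspective": self.perspective.value,
            "discount_rate": self.discount_rate,
            "ly_undiscounted": self.ly_undiscounted,
            "qaly_undiscounted": self.qaly_undiscounted,
            "qaly_discounted": self.qaly_discounted,
            "cost_discounted_societal": self.cost_discounted_societal,
            "cost_discounted_provider": self.cost_discounted_provider,
            "cost_direct_medical": self.cost_direct_medical,
            "cost_direct_nonmedical": self.cost_direct_nonmedical,
            "cost_indirect": self.cost_indirect,
            "cost_undiscounted_societal": self.cost_undiscounted_societal,
            "cost_undiscounted_provider": self.cost_undiscounted_provider,
        }


def accrue_outcomes(
    trace: CohortTrace, params: ModelParameters, settings: AnalysisSettings
) -> PolicyOutcome:
    """Aggregate a cohort trace into lifetime discounted/undiscounted totals.

    Cost streams are discounted at their cycle-start dates, outcome streams
    at their cycle-end dates (the trace carries both clocks).
    """
    if trace.policy != settings.policy:
        raise ParameterError(
            f"trace policy {trace.policy} does not match settings policy {settings.policy}"
        )
    r = settings.discount_rate
    df_out = discount_factor(r, trace.outcome_times)
    df_cost = discount_factor(r, trace.cost_times)
    dm = float(np.sum(trace.cost_direct_medical * df_cost))
    dnm = float(np.sum(trace.cost_direct_nonmedical * df_cost))
    ind = float(np.sum(trace.cost_indirect * df_cost))
    return PolicyOutcome(
        policy=trace.policy,
        perspective=settings.perspective,
        discount_rate=r,
        ly_undiscounted=float(np.sum(trace.ly)),
        qaly_undiscounted=float(np.sum(trace.qaly)),
        qaly_discounted=float(np.sum(trace.qaly * df_out)),
        cost_direct_medical=dm,
        cost_direct_nonmedical=dnm,
        cost_indirect=ind,
        cost_undiscounted_societal=float(
            np.sum(trace.cost_direct_medical)
            + np.sum(trace.cost_direct_nonmedical)
            + np.sum(trace.cost_indirect)
        ),
        cost_undiscounted_provider=float(np.sum(trace.cost_direct_medical)),
    )


def _check_comparable(a: PolicyOutcome, b: PolicyOutcome) -> None:
    if a.discount_rate != b.discount_rate:
        raise ParameterError("outcomes computed with different discount rates")
    if a.perspective != b.perspective:
        raise ParameterError("outcomes computed with different perspectives")


def icer(reference: PolicyOutcome, comparator: PolicyOutcome) -> ICERValue:
    """Incremental cost per QALY of ``comparator`` versus ``reference``.

    Uses discounted costs (active perspective) and discounted QALYs.
    Returns ``"dominated"`` when the comparator costs more for no gain,
    ``"dominant"`` when it costs no more and gains, and ``"equivalent"``
    when both increments are zero.
    """
    _check_comparable(reference, comparator)
    d_cost = comparator.cost_discounted - reference.cost_discounted
    d_eff = comparator.qaly_discounted - reference.qaly_discounted
    if d_cost == 0.0 and d_eff == 0.0:
        return EQUIVALENT
    if d_cost > 0.0 and d_eff <= 0.0:
        return DOMINATED
    if d_cost <= 0.0 and d_eff > 0.0:
        return DOMINANT
    return d_cost / d_eff


def net_monetary_benefit(outcome: PolicyOutcome, wtp: float) -> float:
    """``wtp * discounted QALYs - discounted cost`` in the active perspective."""
    if wtp < 0.0:
        raise ParameterError(f"willingness to pay must be >= 0, got {wtp}")
    return wtp * outcome.qaly_discounted - outcome.cost_discounted


@dataclass(frozen=True)
class CEAResult:
    """Dominance analysis over a set of policy outcomes.

    ``outcomes`` are sorted by discounted QALYs; ``dominance`` maps each
    policy to ``None`` (on the frontier), ``"strict"`` or ``"extended"``;
    ``frontier_icers`` holds sequential ICERs along the efficiency frontier
    as (lower policy, higher policy, IDR/QALY) triples.
    """

    outcomes: tuple[PolicyOutcome, ...]
    dominance: dict
    frontier_icers: tuple[tuple[Policy, Policy, float], ...]

    @property
    def frontier(self) -> tuple[Policy, ...]:
        return tuple(o.policy for o in self.outcomes if self.dominance[o.policy] is None)

    def to_frame(self) -> pd.DataFrame:
        icer_by_policy = {hi: v for _, hi, v in self.frontier_icers}
        rows = []
        for o in self.outcomes:
            row = o.as_dict()
            row["dominance"] = self.dominance[o.policy] or "frontier"
            row["icer_vs_next_on_frontier"] = icer_by_policy.get(o.policy, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def frontier(outcomes: list[PolicyOutcome]) -> CEAResult:
    """Efficiency-frontier construction with strict and extended dominance."""
    if len(outcomes) < 1:
        raise ParameterError("frontier needs at least one outcome")
    for o in outcomes[1:]:
        _check_comparable(outcomes[0], o)
    ranked = sorted(outcomes, key=lambda o: (o.qaly_discounted, o.cost_discounted))
    dominance: dict = {o.policy: None for o in ranked}

    # strict dominance: another option with >= effect and <= cost (one strict)
    for o in ranked:
        for other in ranked:
            if other is o:
                continue
            if (
                other.qaly_discounted >= o.qaly_discounted
                and other.cost_discounted <= o.cost_discounted
                and (
                    other.qaly_discounted > o.qaly_discounted
                    or other.cost_discounted < o.cost_discounted
                )
            ):
                dominance[o.policy] = "strict"
                break

    # extended dominance: drop options until sequential ICERs increase
    def candidates():
        return [o for o in ranked if dominance[o.policy] is None]

    changed = True
    while changed:
        changed = False
        cand = candidates()
        for i in range(1, len(cand) - 1):
            lo, mid, hi = cand[i - 1], cand[i], cand[i + 1]
            icer_lo = _safe_ratio(mid, lo)
            icer_hi = _safe_ratio(hi, mid)
            if icer_lo is not None and icer_hi is not None and icer_hi <= icer_lo:
                dominance[mid.policy] = "extended"
                changed = True
                break

    cand = candidates()
    seq = []
    for lo, hi in zip(cand[:-1], cand[1:]):
        ratio = _safe_ratio(hi, lo)
        if ratio is not None:
            seq.append((lo.policy, hi.policy, ratio))
    return CEAResult(outcomes=tuple(ranked), dominance=dominance, frontier_icers=tuple(seq))


def _safe_ratio(hi: PolicyOutcome, lo: PolicyOutcome) -> float | None:
    d_eff = hi.qaly_discounted - lo.qaly_discounted
    if d_eff <= 0.0:
        return None
    return (hi.cost_discounted - lo.cost_discounted) / d_eff
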