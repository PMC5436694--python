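"""Probabilistic sensitivity analysis and acceptability curves.

Each PSA draw samples every non-fixed parameter from its moment-matched
family (Beta for probabilities and utilities, Gamma for costs; Gamma-family
probabilities are truncated to [0, 1]), runs the full deterministic model
for all three policies on the *same* sampled set (common random numbers,
which reduces the variance of incremental quantities), and records the
per-policy outcomes.  The cost-effectiveness acceptability curve (CEAC)
reports, for each willingness-to-pay value, the fraction of draws in which
each policy attains the highest net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import run_trace
from .outcomes import PolicyOutcome, accrue_outcomes
from .parameters import (
    AnalysisSettings,
    ModelParameters,
    ParameterError,
    ParameterEstimate,
    Perspective,
    Policy,
    SurvivalSchedule,
    validate_parameter_set,
    _PARAM_KIND,
)

__all__ = ["PSAResult", "CEACCurve", "sample_parameter_set", "run_psa", "ceac", "ceac_crossing"]

_POLICIES = (Policy.SUPPORTIVE, Policy.PD_FIRST, Policy.HD_FIRST)


def _draw(est: ParameterEstimate, kind: str, rng: np.random.Generator) -> ParameterEstimate:
    if est.is_fixed:
        return est
    if est.family == "beta":
        a, b = est.natural_params()
        value = float(rng.beta(a, b))
    else:  # gamma
        shape, scale = est.natural_params()
        value = float(rng.gamma(shape, scale))
        if kind in ("probability", "utility"):
            value = min(value, 1.0)  # printed family kept; draws truncated to valid range
    return ParameterEstimate(mean=value, se=est.se, family=est.family)


def check_sampling_feasible(params: ModelParameters) -> None:
    """Raise a configuration error if any non-fixed parameter cannot be sampled."""
    errors = [d for d in validate_parameter_set(params) if d.level == "error"]
    if errors:
        raise ParameterError(
            "parameter set not sampleable: " + "; ".join(d.message for d in errors)
        )


def sample_parameter_set(params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """One Monte-Carlo draw of the full parameter set.

    Parameters with ``se = 0`` (or ``family="fixed"``) pass through
    unchanged.  The draw order is the canonical registry order, so a given
    generator state always yields the same sampled set.
    """
    surv = SurvivalSchedule(
        tuple(_draw(p, "probability", rng) for p in params.survival.annual_death_prob)
    )
    changes = {
        name: _draw(getattr(params, name), _PARAM_KIND[name], rng)
        for name in _PARAM_KIND
    }
    return params.replace(survival=surv, **changes)


@dataclass(frozen=True)
class PSAResult:
    """All per-draw outcomes of one PSA run.

    ``outcomes`` has one row per draw x policy with discounted/undiscounted
    effects and both perspective costs; ``param_draws`` stores each draw's
    sampled parameter means (one column per parameter).
    """

    seed: int
    n_draws: int
    perspective: Perspective
    outcomes: pd.DataFrame
    param_draws: pd.DataFrame

    def cost_column(self) -> str:
        return (
            "cost_discounted_societal"
            if self.perspective is Perspective.SOCIETAL
            else "cost_discounted_provider"
        )

    def mean_outcomes(self) -> pd.DataFrame:
        """Across-draw means of every outcome column, one row per policy."""
        return self.outcomes.groupby("policy", sort=False).mean().drop(columns=["draw"])

    def mean_icer(self, intervention: Policy, reference: Policy) -> float:
        """Across-draw mean of the per-draw ICER of intervention vs reference.

        This is the "average of the simulations" summary; draws with a
        non-positive QALY increment are excluded (their ratio is undefined).
        """
        cost = self.cost_column()
        wide_c = self.outcomes.pivot(index="draw", columns="policy", values=cost)
        wide_q = self.outcomes.pivot(index="draw", columns="policy", values="qaly_discounted")
        d_cost = wide_c[intervention.value] - wide_c[reference.value]
        d_eff = wide_q[intervention.value] - wide_q[reference.value]
        valid = d_eff > 0.0
        if not valid.any():
            return float("nan")
        return float((d_cost[valid] / d_eff[valid]).mean())


def run_psa(params: ModelParameters, settings: AnalysisSettings) -> PSAResult:
    """Run the full three-policy model for ``settings.psa_draws`` parameter draws."""
    check_sampling_feasible(params)
    rng = np.random.default_rng(settings.seed)
    rows = []
    draws_rows = []
    for k in range(settings.psa_draws):
        sampled = sample_parameter_set(params, rng)
        draws_rows.append({name: est.mean for name, est in sampled.items()})
        for policy in _POLICIES:
            s = settings.replace(policy=policy)
            out = accrue_outcomes(run_trace(sampled, s), sampled, s)
            rows.append(
                {
                    "draw": k,
                    "policy": policy.value,
                    "ly_undiscounted": out.ly_undiscounted,
                    "qaly_undiscounted": out.qaly_undiscounted,
                    "qaly_discounted": out.qaly_discounted,
                    "cost_discounted_societal": out.cost_discounted_societal,
                    "cost_discounted_provider": out.cost_discounted_provider,
                }
            )
    return PSAResult(
        seed=settings.seed,
        n_draws=settings.psa_draws,
        perspective=settings.perspective,
        outcomes=pd.DataFrame(rows),
        param_draws=pd.DataFrame(draws_rows),
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability each policy is optimal as a function of willingness to pay."""

    wtp: np.ndarray                      # (n_wtp,) IDR per QALY
    policies: tuple[Policy, ...]
    probabilities: np.ndarray            # (n_wtp, n_policies), rows sum to 1

    def probability(self, policy: Policy) -> np.ndarray:
        return self.probabilities[:, self.policies.index(policy)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wtp": self.wtp})
        for j, p in enumerate(self.policies):
            df[p.value] = self.probabilities[:, j]
        return df


def ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each grid value a draw votes for the policy with the highest net
    monetary benefit; exact ties split the vote equally.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size < 1:
        raise ParameterError("wtp grid must be non-empty")
    cost = psa.cost_column()
    wide_c = psa.outcomes.pivot(index="draw", columns="policy", values=cost)
    wide_q = psa.outcomes.pivot(index="draw", columns="policy", values="qaly_discounted")
    policies = tuple(Policy(p) for p in wide_c.columns)
    C = wide_c.to_numpy()                      # (n_draws, n_pol)
    Q = wide_q.to_numpy()
    probs = np.empty((grid.size, len(policies)))
    for i, w in enumerate(grid):
        nmb = w * Q - C
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        votes = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = votes.mean(axis=0)
    return CEACCurve(wtp=grid, policies=policies, probabilities=probs)


def ceac_crossing(curve: CEACCurve, policy: Policy) -> float | None:
    """Smallest grid WTP at which ``policy`` is the most probable optimum.

    Returns ``None`` ("never") if the policy's probability never strictly
    exceeds every other policy's on the grid.
    """
    if policy not in curve.policies:
        raise ParameterError(f"policy {policy} not present in curve")
    j = curve.policies.index(policy)
    others = np.delete(curve.probabilities, j, axis=1)
    if others.shape[1] == 0:
        return float(curve.wtp[0])
    leads = curve.probabilities[:, j] > others.max(axis=1)
    idx = np.flatnonzero(leads)
    if idx.size == 0:
        return None
    return float(curve.wtp[idx[0]])


def deterministic_outcomes(
    params: ModelParameters, settings: AnalysisSettings
) -> dict[Policy, PolicyOutcome]:
    """Mean-parameter (non-probabilistic) outcomes for all three policies."""
    out = {}
    for policy in _POLICIES:
        s = settings.replace(policy=policy)
        out[policy] = accrue_outcomes(run_trace(params, s), params, s)
    return out
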