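"""Three-state annual Markov cohort model with DALY and cost accumulation.

States are S (alive with schizophrenia), R (recovered) and D (dead).  Each
cycle is one year; the cohort is followed from its start age to age 80.
Death is decomposed by cause (suicide, weight-gain-attributable, other) so
DALYs averted can be attributed the same way.

Conventions (spreadsheet-style, no half-cycle correction):

* state membership is counted at cycle start, discount factor (1+r)^-t with
  t = 0 in the first cycle;
* YLD accrues for S occupancy at each of the T cycle starts;
* deaths during cycle t lose the discounted years a survivor would still
  have accrued inside the horizon, i.e. cycles t+1 .. T-1;
* costs accrue per person-year in state S only (recovered patients are out
  of care).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CostProfile, InterventionEffect, ModelConfig, TransitionParameters

__all__ = [
    "CohortTrace",
    "InvalidTransitionError",
    "build_transition_matrix",
    "build_matrices",
    "run_cohort",
    "accumulate_dalys",
    "accumulate_costs",
    "dalys_averted",
]

_STATES = ("S", "R", "D")
_CAUSES = ("suicide", "weight", "other")


class InvalidTransitionError(ValueError):
    """Exit probabilities from a state exceed 1 before renormalization."""


@dataclass
class CohortTrace:
    """State occupancy per cycle start plus per-cycle deaths by cause.

    ``occupancy`` has shape (T+1, 3) over (S, R, D); ``deaths_by_cause``
    maps cause -> length-T array of deaths occurring during each cycle.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    deaths_by_cause: dict[str, np.ndarray]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self):
        import pandas as pd

        t = self.n_cycles
        return pd.DataFrame(
            {
                "cycle": np.arange(t + 1),
                "age": np.concatenate([self.ages, [self.ages[-1] + 1.0]]),
                "S": self.occupancy[:, 0],
                "R": self.occupancy[:, 1],
                "D": self.occupancy[:, 2],
                "deaths_suicide": np.concatenate([self.deaths_by_cause["suicide"], [0.0]]),
                "deaths_weight": np.concatenate([self.deaths_by_cause["weight"], [0.0]]),
                "deaths_other": np.concatenate([self.deaths_by_cause["other"], [0.0]]),
            }
        )


def build_transition_matrix(
    tp: TransitionParameters, eff: InterventionEffect, age: float
) -> tuple[np.ndarray, dict[str, float]]:
    """One-year transition matrix at a given age for a treated cohort.

    The suicide probability is the base rate times the strategy's relative
    risk; weight-attributable mortality applies the log-linear risk increase
    for the strategy's (adherence-adjusted) weight gain to the baseline
    weight-related mortality — the added share equals minus the potential
    impact fraction of the BMI shift.  Competing exits combine additively;
    a sum above 1 raises rather than silently renormalizing.

    Returns the 3x3 matrix plus the cause-specific death probabilities out
    of S (and the other-cause probability out of R under key ``other_R``).
    """
    wr = tp.weight_risk
    p_sui = tp.p_suicide_base * eff.rr_suicide
    shift = eff.weight_gain_kg / wr.height_m**2
    p_wt = wr.p_weight_related_base * (np.exp(wr.beta_per_bmi_unit * shift) - 1.0)
    p_oth = tp.other_mortality(age)
    p_rem = tp.p_remission
    exits = p_rem + p_sui + p_wt + p_oth
    if exits > 1.0:
        raise InvalidTransitionError(
            f"exit probabilities from S sum to {exits:.4f} > 1 at age {age}"
        )
    if p_oth > 1.0:
        raise InvalidTransitionError(f"other-cause mortality {p_oth} > 1")
    m = np.array(
        [
            [1.0 - exits, p_rem, p_sui + p_wt + p_oth],
            [0.0, 1.0 - p_oth, p_oth],
            [0.0, 0.0, 1.0],
        ]
    )
    causes = {"suicide": p_sui, "weight": p_wt, "other": p_oth, "other_R": p_oth}
    return m, causes


def build_matrices(
    tp: TransitionParameters, eff: InterventionEffect, start_age: float, horizon_age: float
) -> tuple[np.ndarray, np.ndarray, list[dict[str, float]]]:
    """Age-indexed matrices for every cycle from start_age to horizon_age."""
    t = int(round(horizon_age - start_age))
    if t < 1:
        raise ValueError("horizon must exceed start age")
    ages = start_age + np.arange(t, dtype=float)
    mats = np.empty((t, 3, 3))
    causes: list[dict[str, float]] = []
    for i, age in enumerate(ages):
        mats[i], c = build_transition_matrix(tp, eff, age)
        causes.append(c)
    return ages, mats, causes


def run_cohort(
    matrices: np.ndarray,
    cause_probs: list[dict[str, float]],
    start: np.ndarray,
    ages: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate a per-person-normalized occupancy vector through the cycles.

    ``occupancy(t+1) = occupancy(t) @ M(t)``; deaths during cycle t are
    split by cause from the cause-specific probabilities (suicide and weight
    deaths arise from S only, other-cause deaths from both S and R).
    """
    matrices = np.asarray(matrices, dtype=float)
    t = matrices.shape[0]
    if not np.allclose(matrices.sum(axis=2), 1.0, atol=1e-12):
        raise InvalidTransitionError("transition matrix rows must sum to 1")
    start = np.asarray(start, dtype=float)
    occ = np.empty((t + 1, 3))
    occ[0] = start
    deaths = {c: np.zeros(t) for c in _CAUSES}
    for i in range(t):
        s, r, _ = occ[i]
        cp = cause_probs[i]
        deaths["suicide"][i] = s * cp["suicide"]
        deaths["weight"][i] = s * cp["weight"]
        deaths["other"][i] = s * cp["other"] + r * cp["other_R"]
        occ[i + 1] = occ[i] @ matrices[i]
    if ages is None:
        ages = np.arange(t, dtype=float)
    return CohortTrace(ages=np.asarray(ages, dtype=float), occupancy=occ, deaths_by_cause=deaths)


def _discount_factors(n: int, rate: float) -> np.ndarray:
    return (1.0 + rate) ** (-np.arange(n, dtype=float))


def accumulate_dalys(
    trace: CohortTrace, dw: float, config: ModelConfig
) -> dict[str, float | dict[str, float]]:
    """Discounted YLD, YLL (by cause) and total DALYs per starting person.

    YLD applies ``dw`` to S occupancy at each cycle start (the recovered
    state accrues DW 0); deaths in cycle t contribute the discounted years
    t+1 .. T-1 remaining to the horizon.
    """
    if not (0.0 <= dw <= 1.0):
        raise ValueError("disability weight must be in [0, 1]")
    t = trace.n_cycles
    disc = _discount_factors(t, config.discount_rate)
    yld = float(np.sum(disc * trace.occupancy[:-1, 0]) * dw)
    # annuity[t] = sum of disc[u] for u in t+1 .. T-1
    annuity = np.concatenate([np.cumsum(disc[::-1])[::-1][1:], [0.0]])
    yll_by_cause = {
        c: float(np.sum(trace.deaths_by_cause[c] * annuity)) for c in _CAUSES
    }
    yll = sum(yll_by_cause.values())
    return {"YLD": yld, "YLL": yll, "YLL_by_cause": yll_by_cause, "DALY": yld + yll}


def accumulate_costs(
    trace: CohortTrace, cp: CostProfile, config: ModelConfig
) -> dict[str, float]:
    """Discounted cost components per starting person.

    Each component sums ``disc(t) * S(t) * cost-per-person-year``.  The
    family-intervention program (startup amortization, the 10-session course
    and its participant time) is charged in the first cycle; booster-session
    provider and participant-time costs from the second cycle onward.
    """
    t = trace.n_cycles
    disc = _discount_factors(t, config.discount_rate)
    s_occ = trace.occupancy[:-1, 0]
    first = np.zeros(t)
    if t > 0:
        first[0] = 1.0
    later = 1.0 - first
    intervention = cp.drug_admin_cost + first * (
        cp.fi_startup_amortized + cp.fi_session_cost
    ) + later * cp.fi_booster_cost
    time_travel = cp.time_travel_cost + first * cp.fi_time_first_year + later * cp.fi_time_booster
    components = {
        "intervention": float(np.sum(disc * s_occ * intervention)),
        "side_effects": float(np.sum(disc * s_occ * cp.side_effect_cost)),
        "hospitalization": float(np.sum(disc * s_occ * cp.hosp_rate * cp.hosp_unit_cost)),
        "time_travel": float(np.sum(disc * s_occ * time_travel)),
    }
    components["total"] = sum(v for k, v in components.items() if k != "total")
    return components


def dalys_averted(
    strategy_daly: dict, null_daly: dict
) -> dict[str, float]:
    """Decomposed DALYs averted versus the 'do nothing' run.

    ``severity`` is the YLD difference plus the (second-order) other-cause
    YLL difference so the three components sum exactly to the total;
    ``weight_gain`` is negative when the drug's weight gain adds mortality;
    ``suicide`` is the YLL difference from suicide deaths.
    """
    sev = (null_daly["YLD"] - strategy_daly["YLD"]) + (
        null_daly["YLL_by_cause"]["other"] - strategy_daly["YLL_by_cause"]["other"]
    )
    weight = null_daly["YLL_by_cause"]["weight"] - strategy_daly["YLL_by_cause"]["weight"]
    suicide = null_daly["YLL_by_cause"]["suicide"] - strategy_daly["YLL_by_cause"]["suicide"]
    return {
        "severity": sev,
        "weight_gain": weight,
        "suicide": suicide,
        "total": sev + weight + suicide,
    }
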