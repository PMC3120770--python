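"""Model/Results objects tying the pipeline together.

:class:`CEAModel` is built from a :class:`~schizocea.params.ParameterSet`
(plus an optional strategy subset); :meth:`CEAModel.run` evaluates every
strategy against the 'do nothing' comparator and returns a
:class:`CEAResults` carrying per-strategy discounted costs, DALYs averted,
the ACER table, the efficient frontier, and a ``summary()`` text report.
Probabilistic sensitivity analysis and the price sweep hang off the model
object and delegate to :mod:`schizocea.uncertainty`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import economics, markov, meta
from .params import (
    InterventionEffect,
    ParameterSet,
    StrategyDefinition,
    load_parameter_set,
    validate_parameter_set,
)

__all__ = ["StrategyResult", "CEAModel", "CEAResults", "evaluate_strategy"]


@dataclass
class StrategyResult:
    """Discounted outcomes of one strategy versus the 'do nothing' null.

    Monetary fields are 2005 baht and DALY fields are DALYs, both scaled to
    the cohort (``config.cohort_size`` persons).  ``first_year_costs`` are
    undiscounted per-person components in the first cycle, for reporting.
    """

    name: str
    strategy: StrategyDefinition
    cost_components: dict[str, float]
    total_cost: float
    null_cost: float
    net_cost: float
    daly_components: dict[str, float]
    dalys_averted: float
    daly_strategy: float
    daly_null: float
    first_year_costs: dict[str, float]
    severity_fraction: float | None = None


def _stratum_dw_null(ps: ParameterSet, mask: np.ndarray) -> float:
    sm = ps.severity_map
    scores = ps.survey.scores[mask]
    return float(np.mean(sm.dw_min + (scores - sm.score_min) * sm.slope))


def _run_arm(ps: ParameterSet, eff: InterventionEffect, dw: float, cost_key: str):
    cfg = ps.config
    ages, mats, causes = markov.build_matrices(
        ps.transitions, eff, cfg.start_age, cfg.horizon_age
    )
    trace = markov.run_cohort(mats, causes, np.array([1.0, 0.0, 0.0]), ages)
    daly = markov.accumulate_dalys(trace, dw, cfg)
    costs = markov.accumulate_costs(trace, ps.costs[cost_key], cfg)
    return trace, daly, costs


def evaluate_strategy(ps: ParameterSet, strat: StrategyDefinition) -> StrategyResult:
    """Full deterministic pipeline for one strategy.

    Severity-restricted strategies split the cohort at the BPRS cutoff using
    the survey sample; each stratum is evaluated against its own null
    disability weight and results are mixed by the eligible fraction.
    """
    cfg = ps.config
    null_eff = meta.apply_adherence(ps.effects["null"])

    if strat.severity_eligibility is not None:
        cut = strat.severity_eligibility
        masks = [ps.survey.scores > cut, ps.survey.scores <= cut]
        fracs = [float(m.mean()) for m in masks]
        keys = [strat.cost_effect_key(), strat.cost_effect_key(strat.fallback_drug)]
        severity_fraction = fracs[0]
    else:
        masks = [np.ones(ps.survey.scores.size, dtype=bool)]
        fracs = [1.0]
        keys = [strat.cost_effect_key()]
        severity_fraction = None

    scale = cfg.cohort_size
    agg_cost = {k: 0.0 for k in ("intervention", "side_effects", "hospitalization", "time_travel", "total")}
    agg_null_cost = 0.0
    agg_daly = {k: 0.0 for k in ("severity", "weight_gain", "suicide", "total")}
    daly_strategy = daly_null = 0.0
    first_year = {k: 0.0 for k in agg_cost}

    for frac, mask, key in zip(fracs, masks, keys):
        if frac == 0.0:
            continue
        dw_null = _stratum_dw_null(ps, mask)
        eff = meta.apply_adherence(ps.effects[key])
        dw_treat = dw_null + eff.dw_change + eff.dw_change_eps
        if not (0.0 <= dw_treat <= 1.0):
            raise ValueError(
                f"effect for {key!r} drives disability weight to {dw_treat:.3f}"
            )
        _, daly_s, costs_s = _run_arm(ps, eff, dw_treat, key)
        _, daly_n, costs_n = _run_arm(ps, null_eff, dw_null, "null")
        averted = markov.dalys_averted(daly_s, daly_n)
        w = frac * scale
        for k in agg_cost:
            agg_cost[k] += w * costs_s[k]
        agg_null_cost += w * costs_n["total"]
        for k in agg_daly:
            agg_daly[k] += w * averted[k]
        daly_strategy += w * daly_s["DALY"]
        daly_null += w * daly_n["DALY"]
        cp = ps.costs[key]
        fy = {
            "intervention": cp.drug_admin_cost + cp.fi_startup_amortized + cp.fi_session_cost,
            "side_effects": cp.side_effect_cost,
            "hospitalization": cp.hosp_rate * cp.hosp_unit_cost,
            "time_travel": cp.time_travel_cost + cp.fi_time_first_year,
        }
        fy["total"] = sum(fy.values())
        for k in first_year:
            first_year[k] += frac * fy[k]

    return StrategyResult(
        name=strat.name,
        strategy=strat,
        cost_components={k: v for k, v in agg_cost.items() if k != "total"},
        total_cost=agg_cost["total"],
        null_cost=agg_null_cost,
        net_cost=agg_cost["total"] - agg_null_cost,
        daly_components=agg_daly,
        dalys_averted=agg_daly["total"],
        daly_strategy=daly_strategy,
        daly_null=daly_null,
        first_year_costs=first_year,
        severity_fraction=severity_fraction,
    )


class CEAModel:
    """Lifetime Markov cohort cost-effectiveness model.

    Parameters
    ----------
    params
        A validated :class:`ParameterSet`.
    strategies
        Optional subset of strategy names to evaluate; defaults to every
        strategy defined in ``params``.
    """

    def __init__(self, params: ParameterSet, strategies: list[str] | None = None):
        violations = validate_parameter_set(params)
        if violations:
            raise ValueError(
                "invalid parameter set: " + "; ".join(str(v) for v in violations)
            )
        self.params = params
        if strategies is None:
            self.strategies = list(params.strategies)
        else:
            by_name = {s.name: s for s in params.strategies}
            self.strategies = [by_name[n] for n in strategies]

    @classmethod
    def from_file(cls, path: str | Path, strategies: list[str] | None = None) -> "CEAModel":
        return cls(load_parameter_set(path), strategies)

    def run(self) -> "CEAResults":
        results = [evaluate_strategy(self.params, s) for s in self.strategies]
        frontier = economics.icer_frontier(
            [(sr.name, sr.net_cost, sr.dalys_averted) for sr in results]
        )
        return CEAResults(model=self, results=results, frontier=frontier)

    # evaluating a decision model plays the role fitting plays for a
    # statistical one; keep the familiar spelling available
    fit = run

    def run_psa(self, n_draws: int = 2000, seed: int = 0, thresholds=None):
        from . import uncertainty

        return uncertainty.run_psa(
            self.params, [s.name for s in self.strategies], n_draws, seed, thresholds
        )

    def price_sweep(self, drug: str, prices, comparator: str):
        from . import uncertainty

        return uncertainty.price_sweep(self.params, drug, prices, comparator)

    def threshold_price(self, drug: str, comparator: str, criterion="dominance", bracket=(4.0, 50.0)):
        from . import uncertainty

        return uncertainty.threshold_price(self.params, drug, comparator, criterion, bracket)


@dataclass
class CEAResults:
    """Deterministic run output: strategy results, frontier, tables."""

    model: CEAModel
    results: list[StrategyResult]
    frontier: list[economics.FrontierStep]
    _by_name: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {sr.name: sr for sr in self.results}

    def __getitem__(self, name: str) -> StrategyResult:
        return self._by_name[name]

    def tables(self):
        return economics.render_results_tables(
            self.results, self.frontier, self.model.params.config
        )

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables().items():
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        return written

    def summary(self) -> str:
        cfg = self.model.params.config
        t = self.tables()
        lines = [
            "Cost-effectiveness of schizophrenia interventions vs 'do nothing'",
            f"cohort: {cfg.cohort_size:,.0f} persons from age {cfg.start_age:.0f} "
            f"to {cfg.horizon_age:.0f}, discount {cfg.discount_rate:.0%}",
            "",
            "DALYs averted (cohort, discounted)",
            t["health_effects"].to_string(index=False),
            "",
            "First-year costs per person (baht, undiscounted)",
            t["first_year_costs"].to_string(index=False),
            "",
            "Average cost-effectiveness vs null (baht, DALYs)",
            t["acer"].to_string(index=False),
            "",
            "Efficient intervention pathway (incremental, baht/DALY)",
            t["frontier"].to_string(index=False),
        ]
        return "\n".join(lines)
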