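"""Cost-effectiveness ratios, dominance, the ICER frontier, and reporting.

Costs here are *net* discounted costs versus the 'do nothing' comparator
(baht) and effects are DALYs averted versus the same comparator, so the
null sits at (0, 0) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import math

import pandas as pd

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "EXTENDED_DOMINATED",
    "FrontierStep",
    "average_cer",
    "icer_frontier",
    "round_report",
    "render_results_tables",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"


@dataclass(frozen=True)
class FrontierStep:
    """One retained step of the efficient intervention pathway.

    ``icer`` is baht per DALY averted versus the previous retained step, or
    ``None`` when the step is cost-saving (``classification == 'dominant'``).
    """

    strategy: str
    incremental_cost: float
    incremental_effect: float
    icer: float | None
    classification: str = ""


def average_cer(net_cost: float, effect: float) -> float | str:
    """Average cost-effectiveness ratio versus the null, or a dominance label.

    Cost-saving and more effective -> ``'dominant'``; costlier and less
    effective -> ``'dominated'``; zero effect is an undefined ratio.
    """
    if effect == 0.0:
        raise ZeroDivisionError("ACER undefined for zero DALYs averted")
    if net_cost < 0.0 and effect > 0.0:
        return DOMINANT
    if net_cost > 0.0 and effect < 0.0:
        return DOMINATED
    return net_cost / effect


def icer_frontier(strategies: list[tuple[str, float, float]]) -> list[FrontierStep]:
    """Efficient frontier over (name, net cost, DALYs averted) points.

    The null (0, 0) is an implicit candidate anchor.  Strategies are sorted
    by cost; strictly dominated points (costlier, not more effective than a
    cheaper one) are removed, then extended dominance is applied iteratively
    until ICERs strictly increase along the retained chain.  Steps report
    incremental quantities versus the previous retained point; a retained
    step that is cheaper than its predecessor-anchor and more effective is
    classified 'dominant' and carries no ICER.

    Ties: equal cost and effect keep the lexicographically-first name; equal
    cost with different effect keeps the higher effect.
    """
    pts = [("", 0.0, 0.0)] + [(n, float(c), float(e)) for n, c, e in strategies]
    # sort: cost asc, effect desc, name asc — makes both tie rules a
    # consequence of plain dominance removal below
    pts.sort(key=lambda p: (p[1], -p[2], p[0]))
    # simple dominance: keep only points strictly increasing in effect
    retained: list[tuple[str, float, float]] = []
    best_effect = -math.inf
    for p in pts:
        if p[2] > best_effect:
            retained.append(p)
            best_effect = p[2]
        elif p[2] == best_effect and retained and p[1] == retained[-1][1]:
            # exact duplicate of the last retained point: first name wins
            continue
    # extended dominance: drop interior points until ICERs strictly increase
    def icers(chain):
        out = []
        for a, b in zip(chain[:-1], chain[1:]):
            de = b[2] - a[2]
            dc = b[1] - a[1]
            out.append(dc / de if de > 0 else math.inf)
        return out

    changed = True
    while changed and len(retained) > 2:
        changed = False
        slopes = icers(retained)
        for i in range(len(slopes) - 1):
            if slopes[i] >= slopes[i + 1]:
                del retained[i + 1]
                changed = True
                break

    steps: list[FrontierStep] = []
    prev = None
    for p in retained:
        if prev is not None and p[0] != "":
            dc, de = p[1] - prev[1], p[2] - prev[2]
            if dc <= 0.0 and de > 0.0:
                steps.append(FrontierStep(p[0], dc, de, None, DOMINANT))
            else:
                steps.append(FrontierStep(p[0], dc, de, dc / de, ""))
        elif prev is None and p[0] != "":
            # cheapest retained point is a strategy: its step is vs the null
            if p[1] < 0.0 and p[2] > 0.0:
                steps.append(FrontierStep(p[0], p[1], p[2], None, DOMINANT))
            else:
                steps.append(
                    FrontierStep(p[0], p[1], p[2], p[1] / p[2] if p[2] > 0 else None, "")
                )
        prev = p
    return steps


def round_report(x: float, sigfigs: int) -> float:
    """Half-up rounding to a number of significant figures.

    Half-up (not banker's) so e.g. 625,000 reports as 630,000 at two
    significant figures, matching conventional table formatting.
    """
    if sigfigs < 1:
        raise ValueError("sigfigs must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(abs(x))))
    exponent = d.adjusted()  # floor(log10(|x|))
    quantum = Decimal(1).scaleb(exponent - sigfigs + 1)
    rounded = d.quantize(quantum, rounding=ROUND_HALF_UP)
    return math.copysign(float(rounded), x)


def render_results_tables(results, frontier, config) -> dict[str, pd.DataFrame]:
    """Assemble the reporting tables from strategy results and the frontier.

    Produces per-strategy DALY decompositions, first-year cost components,
    ACERs with dominance labels, and the frontier with ICERs; every numeric
    value passes through :func:`round_report` at ``config.report_sigfigs``.
    ``results`` is a list of :class:`schizocea.model.StrategyResult`.
    """
    sf = config.report_sigfigs
    r = lambda x: round_report(x, sf)

    health = pd.DataFrame(
        [
            {
                "strategy": sr.name,
                "severity": r(sr.daly_components["severity"]),
                "weight_gain": r(sr.daly_components["weight_gain"]),
                "suicide": r(sr.daly_components["suicide"]),
                "total": r(sr.daly_components["total"]),
            }
            for sr in results
        ]
    )
    costs = pd.DataFrame(
        [
            {
                "strategy": sr.name,
                "intervention": r(sr.first_year_costs["intervention"]),
                "side_effects": r(sr.first_year_costs["side_effects"]),
                "hospitalization": r(sr.first_year_costs["hospitalization"]),
                "time_travel": r(sr.first_year_costs["time_travel"]),
                "total": r(sr.first_year_costs["total"]),
            }
            for sr in results
        ]
    )
    acer_rows = []
    for sr in results:
        try:
            acer = average_cer(sr.net_cost, sr.dalys_averted)
        except ZeroDivisionError:
            acer = "undefined"
        acer_rows.append(
            {
                "strategy": sr.name,
                "net_cost": r(sr.net_cost),
                "dalys_averted": r(sr.dalys_averted),
                "acer": acer if isinstance(acer, str) else r(acer),
            }
        )
    acers = pd.DataFrame(acer_rows)
    frontier_df = pd.DataFrame(
        [
            {
                "strategy": st.strategy,
                "incremental_cost": r(st.incremental_cost),
                "incremental_effect": r(st.incremental_effect),
                "icer": st.classification if st.icer is None else r(st.icer),
            }
            for st in frontier
        ],
        columns=["strategy", "incremental_cost", "incremental_effect", "icer"],
    )
    return {
        "health_effects": health,
        "first_year_costs": costs,
        "acer": acers,
        "frontier": frontier_df,
    }
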