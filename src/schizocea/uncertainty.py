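"""Monte Carlo uncertainty propagation, CEACs, and the price sensitivity sweep.

Every uncertain parameter carries a :class:`~schizocea.params.DistributionSpec`
keyed by dotted path; :func:`sample_parameter_set` draws one realization,
:func:`run_psa` propagates draws through the full deterministic pipeline and
summarizes (cost, effect) clouds per strategy as percentile intervals and
cost-effectiveness acceptability probabilities.  Acceptability is computed
on net monetary benefit (NMB = threshold * effect - cost): per-draw ICER
thresholds are ill-defined under dominance, NMB is the standard resolution.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import economics
from .model import evaluate_strategy
from .params import ParameterSet, set_by_path, validate_parameter_set

__all__ = [
    "PSAOutput",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "price_sweep",
    "threshold_price",
]

_MAX_REDRAWS = 100


def sample_parameter_set(
    ps: ParameterSet, rng: np.random.Generator | int
) -> ParameterSet:
    """One Monte Carlo draw of the parameter set.

    Point-distributed (or unlisted) parameters are left untouched.  A draw
    that violates any type invariant is rejected and redrawn, up to a
    bounded retry count.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for _ in range(_MAX_REDRAWS):
        draw = copy.deepcopy(ps)
        for path, spec in ps.distributions.items():
            set_by_path(draw, path, spec.draw(rng))
        for cp in draw.costs.values():
            # a drawn drug+administration cost moves the administration
            # share; the tablet price stays at its configured value
            if cp.tablets_per_day is not None and cp.tablet_price is not None:
                cp.admin_visit_cost = (
                    cp.drug_admin_cost - cp.tablets_per_day * 365.0 * cp.tablet_price
                )
        if not validate_parameter_set(draw):
            return draw
    raise RuntimeError(f"no valid parameter draw after {_MAX_REDRAWS} attempts")


@dataclass
class PSAOutput:
    """Monte Carlo (cost, effect) draws per strategy with derived summaries.

    ``costs``/``effects`` have shape (n_draws, n_strategies): net discounted
    cohort cost (baht) and DALYs averted versus the null.  ``ceac`` maps
    threshold -> per-strategy probability of positive NMB vs the null;
    ``step_ceac`` maps threshold -> per-frontier-step probability that the
    step's *incremental* NMB (vs the previous retained step) is positive.
    """

    strategy_names: list[str]
    costs: np.ndarray
    effects: np.ndarray
    n_draws: int
    seed: int
    n_failed: int = 0
    intervals: dict = field(default_factory=dict)
    ceac: dict = field(default_factory=dict)
    step_ceac: dict = field(default_factory=dict)
    step_names: list[str] = field(default_factory=list)


def ceac(
    costs: np.ndarray, effects: np.ndarray, thresholds
) -> dict[float, np.ndarray]:
    """P(NMB > 0) per strategy column over a threshold grid."""
    out = {}
    for lam in thresholds:
        nmb = lam * effects - costs
        out[float(lam)] = (nmb > 0).mean(axis=0)
    return out


def run_psa(
    ps: ParameterSet,
    strategies: list[str],
    n_draws: int,
    seed: int,
    thresholds=None,
) -> PSAOutput:
    """Propagate ``n_draws`` parameter draws through the full pipeline.

    Reproducible: identical (parameter set, seed, n_draws) give identical
    output.  Draws whose model evaluation fails an invariant (e.g. a DW
    pushed outside [0, 1]) are dropped and counted in ``n_failed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cfg = ps.config
    if thresholds is None:
        thresholds = (cfg.wtp_threshold_1x, cfg.wtp_threshold_3x)
    by_name = {s.name: s for s in ps.strategies}
    strat_defs = [by_name[n] for n in strategies]
    rng = np.random.default_rng(seed)

    rows_c, rows_e = [], []
    n_failed = 0
    for _ in range(n_draws):
        draw = sample_parameter_set(ps, rng)
        try:
            res = [evaluate_strategy(draw, s) for s in strat_defs]
        except ValueError:
            n_failed += 1
            continue
        rows_c.append([r.net_cost for r in res])
        rows_e.append([r.dalys_averted for r in res])
    if not rows_c:
        raise RuntimeError("every PSA draw failed model invariants")
    costs = np.array(rows_c)
    effects = np.array(rows_e)

    qs = (2.5, 50.0, 97.5)
    intervals = {
        "cost": {q: np.percentile(costs, q, axis=0) for q in qs},
        "effect": {q: np.percentile(effects, q, axis=0) for q in qs},
    }

    # incremental acceptability along the deterministic frontier
    base = [evaluate_strategy(ps, s) for s in strat_defs]
    frontier = economics.icer_frontier(
        [(r.name, r.net_cost, r.dalys_averted) for r in base]
    )
    idx = {n: i for i, n in enumerate(strategies)}
    step_ceac: dict[float, np.ndarray] = {}
    step_names = [st.strategy for st in frontier]
    for lam in thresholds:
        probs = []
        prev = None
        for st in frontier:
            j = idx[st.strategy]
            dc = costs[:, j] - (costs[:, prev] if prev is not None else 0.0)
            de = effects[:, j] - (effects[:, prev] if prev is not None else 0.0)
            probs.append(float(np.mean(lam * de - dc > 0)))
            prev = j
        step_ceac[float(lam)] = np.array(probs)

    return PSAOutput(
        strategy_names=list(strategies),
        costs=costs,
        effects=effects,
        n_draws=n_draws,
        seed=seed,
        n_failed=n_failed,
        intervals=intervals,
        ceac=ceac(costs, effects, thresholds),
        step_ceac=step_ceac,
        step_names=step_names,
    )


def _with_price(ps: ParameterSet, drug: str, price: float) -> ParameterSet:
    """Copy of ``ps`` with the drug's tablet price reset (all profiles using it)."""
    out = copy.deepcopy(ps)
    touched = False
    for key in (drug, f"fi_{drug}"):
        cp = out.costs.get(key)
        if cp is None:
            continue
        if cp.tablets_per_day is None or cp.admin_visit_cost is None:
            raise ValueError(f"cost profile {key!r} has no tablet pricing fields")
        cp.tablet_price = float(price)
        cp.drug_admin_cost = cp.admin_visit_cost + cp.tablets_per_day * 365.0 * price
        touched = True
    if not touched:
        raise KeyError(f"no cost profile for drug {drug!r}")
    return out


def _incremental(ps: ParameterSet, drug: str, comparator: str, price: float):
    drawn = _with_price(ps, drug, price)
    by_name = {s.name: s for s in drawn.strategies}
    r_drug = evaluate_strategy(drawn, by_name[drug])
    r_comp = evaluate_strategy(drawn, by_name[comparator])
    return r_drug.net_cost - r_comp.net_cost, r_drug.dalys_averted - r_comp.dalys_averted


def price_sweep(
    ps: ParameterSet, drug: str, prices, comparator: str
) -> list[dict]:
    """One-way sensitivity of the drug-vs-comparator ICER to tablet price.

    For each price the drug-plus-administration cost is recomputed from the
    daily dose and the full model rerun; each row reports the incremental
    cost/effect versus the comparator and an ICER or dominance label.
    """
    prices = [float(p) for p in prices]
    if not prices or min(prices) <= 0:
        raise ValueError("prices must be nonempty and positive")
    rows = []
    for price in prices:
        dc, de = _incremental(ps, drug, comparator, price)
        if dc < 0 and de > 0:
            icer, label = None, economics.DOMINANT
        elif dc > 0 and de < 0:
            icer, label = None, economics.DOMINATED
        else:
            icer, label = dc / de, ""
        rows.append(
            {
                "price": price,
                "incremental_cost": dc,
                "incremental_effect": de,
                "icer": icer,
                "classification": label,
            }
        )
    return rows


def threshold_price(
    ps: ParameterSet,
    drug: str,
    comparator: str,
    criterion: str | float = "dominance",
    bracket: tuple[float, float] = (4.0, 50.0),
    tol: float = 0.01,
) -> float:
    """Tablet price at which the drug crosses a cost-effectiveness criterion.

    ``criterion='dominance'`` finds the price where incremental cost versus
    the comparator is zero (below it the drug is cost-saving); a numeric
    criterion is a willingness-to-pay threshold (baht/DALY) and finds where
    the incremental net monetary benefit at that threshold is zero, i.e.
    where the ICER equals the threshold.  Bisection to ``tol`` baht.
    """

    if criterion == "dominance":
        f = lambda p: _incremental(ps, drug, comparator, p)[0]
    else:
        lam = float(criterion)

        def f(p):
            dc, de = _incremental(ps, drug, comparator, p)
            return dc - lam * de  # zero where ICER == threshold

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"criterion does not change sign over bracket: f({lo})={f_lo:.6g}, f({hi})={f_hi:.6g}"
        )
    return float(optimize.bisect(f, lo, hi, xtol=tol))
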