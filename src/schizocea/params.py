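"""Parameter containers, validation and YAML/JSON round-tripping.

Everything a single model run needs — discounting and horizon settings,
annual transition parameters, per-strategy intervention effects and cost
profiles, the BPRS-E severity-to-disability-weight map, the severity survey
sample, and optional uncertainty distributions — lives in one
:class:`ParameterSet`.  Currency fields are 2005 Thai baht throughout; no
inflation machinery is provided (inputs are assumed pre-adjusted).

Validation never raises on bad *values*: :func:`validate_parameter_set`
returns a list of :class:`Violation` records naming the offending field and
rule, so callers (and the CLI) can report every problem at once.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ModelConfig",
    "DistributionSpec",
    "WeightRiskModel",
    "TransitionParameters",
    "EpsParameters",
    "SeverityMap",
    "SurveySample",
    "InterventionEffect",
    "CostProfile",
    "StrategyDefinition",
    "ParameterSet",
    "Violation",
    "load_parameter_set",
    "save_parameter_set",
    "validate_parameter_set",
    "resolve_path",
    "set_by_path",
]


class ParameterFileError(ValueError):
    """Raised when a parameter file is structurally unreadable."""


@dataclass
class ModelConfig:
    """Run-level settings.

    ``wtp_threshold_1x``/``wtp_threshold_3x`` are the Thai willingness-to-pay
    anchors of one and three times 2005 GDP per capita (baht per DALY
    averted).  Cycle length is fixed at one year.
    """

    discount_rate: float = 0.03
    horizon_age: float = 80.0
    cycle_length: float = 1.0
    start_age: float = 30.0
    start_year: int = 2005
    cohort_size: float = 370_000.0
    wtp_threshold_1x: float = 110_000.0
    wtp_threshold_3x: float = 330_000.0
    report_sigfigs: int = 2
    rng_seed: int = 0


_DIST_KINDS = {"point", "normal", "lognormal", "beta", "gamma", "uniform"}

# parameter names whose values are fractions/probabilities in [0, 1] —
# the only quantities a beta distribution may be attached to
_FRACTION_FIELDS = {
    "p_remission",
    "p_suicide_base",
    "p_weight_related_base",
    "hosp_rate",
    "adherence",
    "severe_share",
    "p_eps_typicals",
    "p_eps_atypicals",
}

# signed quantities: gamma/lognormal (nonnegative support) are disallowed
_SIGNED_FIELDS = {"dw_change", "dw_change_eps"}

_DIST_PARAM_NAMES = {
    "point": ["value"],
    "normal": ["mean", "sd"],
    "lognormal": ["mean_log", "sd_log"],
    "beta": ["alpha", "beta"],
    "gamma": ["shape", "scale"],
    "uniform": ["low", "high"],
}


@dataclass
class DistributionSpec:
    """One uncertain parameter's sampling distribution."""

    kind: str = "point"
    params: dict[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.kind == "point":
            return float(p["value"])
        if self.kind == "normal":
            return float(rng.normal(p["mean"], p["sd"]))
        if self.kind == "lognormal":
            return float(rng.lognormal(p["mean_log"], p["sd_log"]))
        if self.kind == "beta":
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.kind == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.kind == "uniform":
            return float(rng.uniform(p["low"], p["high"]))
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})

    @classmethod
    def beta_from_moments(cls, mean: float, sd: float) -> "DistributionSpec":
        """Beta spec matching a mean and SD (moment matching)."""
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        if nu <= 0:
            raise ValueError("beta moments infeasible (sd too large for mean)")
        return cls("beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu})

    @classmethod
    def gamma_from_moments(cls, mean: float, sd: float) -> "DistributionSpec":
        """Gamma spec matching a mean and SD."""
        return cls("gamma", {"shape": (mean / sd) ** 2, "scale": sd**2 / mean})


@dataclass
class WeightRiskModel:
    """Log-linear mortality risk for antipsychotic weight gain.

    Weight gain in kg converts to a BMI shift via ``kg / height_m**2``;
    mortality risk scales as ``exp(beta_per_bmi_unit * shift)`` applied to a
    baseline weight-related annual death probability.
    """

    beta_per_bmi_unit: float = 0.05
    height_m: float = 1.6
    p_weight_related_base: float = 0.003


@dataclass
class TransitionParameters:
    """Annual transition inputs for the three-state cohort model.

    ``p_other_mortality`` is a list of ``[age_from, probability]`` bands in
    ascending age order.  ``provenance`` marks these values as synthetic
    placeholders rather than published estimates.
    """

    p_remission: float = 0.02
    p_suicide_base: float = 0.005
    p_other_mortality: list[list[float]] = field(
        default_factory=lambda: [
            [0.0, 0.002],
            [40.0, 0.004],
            [50.0, 0.008],
            [60.0, 0.016],
            [70.0, 0.035],
        ]
    )
    weight_risk: WeightRiskModel = field(default_factory=WeightRiskModel)
    provenance: str = "synthetic"

    def other_mortality(self, age: float) -> float:
        p = self.p_other_mortality[0][1]
        for age_from, prob in self.p_other_mortality:
            if age >= age_from:
                p = prob
        return float(p)


@dataclass
class EpsParameters:
    """Extrapyramidal side-effect inputs.

    Proportions affected on typicals (25%) vs atypicals (13%), with Dutch
    disability weights 0.422 (moderate) and 0.453 (severe EPS); the
    moderate/severe split among those affected is not published, so
    ``severe_share`` defaults to 0.5.
    """

    p_eps_typicals: float = 0.25
    p_eps_atypicals: float = 0.13
    dw_moderate: float = 0.422
    dw_severe: float = 0.453
    severe_share: float = 0.5


@dataclass
class SeverityMap:
    """Linear BPRS-E score → disability weight map.

    Anchors the BPRS-E range (24 = least severe, 134 = most severe) to the
    Dutch disability weights for schizophrenia, 0.21–0.98.
    """

    score_min: float = 24.0
    score_max: float = 134.0
    dw_min: float = 0.21
    dw_max: float = 0.98

    @property
    def slope(self) -> float:
        return (self.dw_max - self.dw_min) / (self.score_max - self.score_min)


@dataclass(eq=False)
class SurveySample:
    """BPRS-E scores from a cross-sectional severity survey."""

    scores: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1))

    def fraction_above(self, cutoff: float) -> float:
        return float(np.mean(self.scores > cutoff))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SurveySample) and np.array_equal(
            self.scores, other.scores
        )


@dataclass
class InterventionEffect:
    """Per-strategy health effects relative to 'do nothing'.

    ``dw_change`` is the severity disability-weight change (negative =
    improvement), ``dw_change_eps`` the extra DW change from the EPS
    differential vs typicals.  Effects here are *pre-adherence*; see
    :func:`schizocea.meta.apply_adherence`.
    """

    dw_change: float = 0.0
    dw_change_eps: float = 0.0
    rr_suicide: float = 1.0
    weight_gain_kg: float = 0.0
    adherence: float = 1.0


@dataclass
class CostProfile:
    """Annual per-person costs (2005 baht) while alive with schizophrenia.

    The ``fi_*`` fields are zero for strategies without family intervention.
    The 10-session program and its participant time cost accrue in the first
    cycle only; booster-session costs accrue from the second cycle onward.
    Optional pricing fields (``tablets_per_day``, ``tablet_price``,
    ``admin_visit_cost``) decompose ``drug_admin_cost`` for price sweeps:
    ``drug_admin_cost = admin_visit_cost + tablets_per_day * 365 * tablet_price``.
    """

    drug_admin_cost: float = 0.0
    side_effect_cost: float = 0.0
    hosp_rate: float = 0.0
    hosp_unit_cost: float = 0.0
    time_travel_cost: float = 0.0
    fi_startup_amortized: float = 0.0
    fi_session_cost: float = 0.0
    fi_booster_cost: float = 0.0
    fi_time_first_year: float = 0.0
    fi_time_booster: float = 0.0
    tablets_per_day: float | None = None
    tablet_price: float | None = None
    admin_visit_cost: float | None = None


@dataclass
class StrategyDefinition:
    """One mutually exclusive treatment strategy.

    ``severity_eligibility`` restricts ``drug`` to the survey stratum above a
    BPRS cutoff; ``fallback_drug`` treats the rest.  The eligible fraction is
    always derived from the survey score distribution at evaluation time.
    """

    name: str
    drug: str = "none"
    family_intervention: bool = False
    severity_eligibility: float | None = None
    fallback_drug: str | None = None

    def cost_effect_key(self, drug: str | None = None) -> str:
        d = self.drug if drug is None else drug
        return f"fi_{d}" if self.family_intervention else d


@dataclass
class ParameterSet:
    """Everything one deterministic model run consumes."""

    config: ModelConfig = field(default_factory=ModelConfig)
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    eps: EpsParameters = field(default_factory=EpsParameters)
    severity_map: SeverityMap = field(default_factory=SeverityMap)
    survey: SurveySample = field(default_factory=SurveySample)
    effects: dict[str, InterventionEffect] = field(default_factory=dict)
    costs: dict[str, CostProfile] = field(default_factory=dict)
    strategies: list[StrategyDefinition] = field(default_factory=list)
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["survey"] = {"scores": [float(s) for s in self.survey.scores]}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        def build(klass, sub, path):
            if sub is None:
                return klass()
            if not isinstance(sub, dict):
                raise ParameterFileError(f"section {path!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ParameterFileError(
                    f"unknown field(s) {sorted(unknown)} in section {path!r}"
                )
            return klass(**sub)

        d = dict(d or {})
        tr = dict(d.get("transitions") or {})
        if "weight_risk" in tr:
            tr["weight_risk"] = build(WeightRiskModel, tr["weight_risk"], "transitions.weight_risk")
        ps = cls(
            config=build(ModelConfig, d.get("config"), "config"),
            transitions=build(TransitionParameters, tr or None, "transitions"),
            eps=build(EpsParameters, d.get("eps"), "eps"),
            severity_map=build(SeverityMap, d.get("severity_map"), "severity_map"),
            survey=SurveySample(np.asarray((d.get("survey") or {}).get("scores", []), dtype=float)),
            effects={
                k: build(InterventionEffect, v, f"effects.{k}")
                for k, v in (d.get("effects") or {}).items()
            },
            costs={
                k: build(CostProfile, v, f"costs.{k}")
                for k, v in (d.get("costs") or {}).items()
            },
            strategies=[
                build(StrategyDefinition, s, f"strategies[{i}]")
                for i, s in enumerate(d.get("strategies") or [])
            ],
            distributions={
                k: build(DistributionSpec, v, f"distributions.{k}")
                for k, v in (d.get("distributions") or {}).items()
            },
        )
        _coerce_numbers(ps)
        return ps


def _coerce_numbers(ps: ParameterSet) -> None:
    """Coerce numeric leaves to float, raising a located error on junk."""

    text_fields = {"provenance"}

    def coerce(obj: Any, path: str) -> None:
        for f in dataclasses.fields(obj):
            val = getattr(obj, f.name)
            here = f"{path}.{f.name}"
            if dataclasses.is_dataclass(val) and not isinstance(val, type):
                coerce(val, here)
            elif (
                f.name in text_fields
                or isinstance(val, (bool, int))
                or val is None
                or isinstance(val, (list, dict, np.ndarray))
            ):
                continue
            else:
                try:
                    setattr(obj, f.name, float(val))
                except (TypeError, ValueError) as exc:
                    raise ParameterFileError(f"malformed number at {here}: {val!r}") from exc

    coerce(ps.config, "config")
    coerce(ps.transitions, "transitions")
    coerce(ps.eps, "eps")
    coerce(ps.severity_map, "severity_map")
    for k, v in ps.effects.items():
        coerce(v, f"effects.{k}")
    for k, v in ps.costs.items():
        coerce(v, f"costs.{k}")


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Read a YAML (or JSON) parameter file, applying documented defaults.

    Fields absent from the file take their defaults (3% discounting, age-80
    horizon, 110,000 / 330,000 baht per DALY thresholds, ...); parameters
    without a distribution entry behave as point values under uncertainty
    analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParameterFileError(f"cannot parse {path}: {exc}") from exc
    ps = ParameterSet.from_dict(raw or {})
    violations = validate_parameter_set(ps)
    if violations:
        msgs = "; ".join(str(v) for v in violations)
        raise ParameterFileError(f"invalid parameter file {path}: {msgs}")
    return ps


def save_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write a normalized parameter dump (YAML, or JSON for ``.json``)."""
    path = Path(path)
    d = ps.to_dict()
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(d, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(d, fh, sort_keys=True)


# -- validation ----------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


def _prob(report: list[Violation], path: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.append(Violation(path, f"probability out of [0,1]: {value}"))


def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Check every type invariant; returns an empty list iff all hold.

    Pure: never mutates ``ps`` and never raises on value errors.
    """
    report: list[Violation] = []
    cfg = ps.config
    if not (0.0 <= cfg.discount_rate < 1.0):
        report.append(Violation("config.discount_rate", "must be in [0, 1)"))
    if cfg.horizon_age <= cfg.start_age:
        report.append(Violation("config.horizon_age", "must exceed start_age"))
    if cfg.wtp_threshold_3x < cfg.wtp_threshold_1x:
        report.append(Violation("config.wtp_threshold_3x", "must be >= wtp_threshold_1x"))
    if cfg.cycle_length != 1.0:
        report.append(Violation("config.cycle_length", "cycle length is fixed at 1 year"))
    if cfg.report_sigfigs < 1:
        report.append(Violation("config.report_sigfigs", "must be >= 1"))

    tr = ps.transitions
    _prob(report, "transitions.p_remission", tr.p_remission)
    _prob(report, "transitions.p_suicide_base", tr.p_suicide_base)
    _prob(report, "transitions.weight_risk.p_weight_related_base", tr.weight_risk.p_weight_related_base)
    ages = [b[0] for b in tr.p_other_mortality]
    if ages != sorted(ages):
        report.append(Violation("transitions.p_other_mortality", "age bands must be ascending"))
    for i, (_, p) in enumerate(tr.p_other_mortality):
        _prob(report, f"transitions.p_other_mortality[{i}]", p)

    eps = ps.eps
    for name in ("p_eps_typicals", "p_eps_atypicals", "severe_share"):
        _prob(report, f"eps.{name}", getattr(eps, name))
    if eps.dw_moderate > eps.dw_severe:
        report.append(Violation("eps.dw_moderate", "must be <= dw_severe"))

    sm = ps.severity_map
    if not sm.score_min < sm.score_max:
        report.append(Violation("severity_map.score_min", "must be < score_max"))
    if not (0.0 <= sm.dw_min < sm.dw_max <= 1.0):
        report.append(Violation("severity_map.dw_min", "need 0 <= dw_min < dw_max <= 1"))

    if ps.survey.scores.size:
        if ps.survey.scores.min() < sm.score_min or ps.survey.scores.max() > sm.score_max:
            report.append(Violation("survey.scores", "scores outside severity map range"))
        if ps.survey.scores.size >= 2 and ps.survey.sd <= 0:
            report.append(Violation("survey.scores", "zero score variance"))

    for key, eff in ps.effects.items():
        base = f"effects.{key}"
        _prob(report, f"{base}.adherence", eff.adherence)
        if eff.rr_suicide <= 0:
            report.append(Violation(f"{base}.rr_suicide", "must be > 0"))

    for key, cp in ps.costs.items():
        base = f"costs.{key}"
        for name in (
            "drug_admin_cost",
            "side_effect_cost",
            "hosp_unit_cost",
            "time_travel_cost",
            "fi_startup_amortized",
            "fi_session_cost",
            "fi_booster_cost",
            "fi_time_first_year",
            "fi_time_booster",
        ):
            if getattr(cp, name) < 0:
                report.append(Violation(f"{base}.{name}", "cost must be >= 0"))
        _prob(report, f"{base}.hosp_rate", cp.hosp_rate)
        if cp.tablet_price is not None and cp.admin_visit_cost is not None and cp.tablets_per_day is not None:
            implied = cp.admin_visit_cost + cp.tablets_per_day * 365.0 * cp.tablet_price
            if not math.isclose(implied, cp.drug_admin_cost, rel_tol=1e-9, abs_tol=0.51):
                report.append(
                    Violation(f"{base}.drug_admin_cost", "inconsistent with tablet pricing fields")
                )

    for st in ps.strategies:
        keys = [st.cost_effect_key()]
        if st.severity_eligibility is not None and st.fallback_drug:
            keys.append(st.cost_effect_key(st.fallback_drug))
        for k in keys:
            if k not in ps.effects:
                report.append(Violation(f"effects.{k}", f"missing for strategy {st.name!r}"))
            if k not in ps.costs:
                report.append(Violation(f"costs.{k}", f"missing for strategy {st.name!r}"))
    if ps.strategies and "null" not in ps.effects:
        report.append(Violation("effects.null", "comparator entry missing"))
    if ps.strategies and "null" not in ps.costs:
        report.append(Violation("costs.null", "comparator entry missing"))

    # net-of-effect DW must stay inside [0, 1] for every strategy stratum
    if ps.survey.scores.size:
        dw_all = sm.dw_min + (ps.survey.scores - sm.score_min) * sm.slope
        dw_null = float(dw_all.mean())
        for key, eff in ps.effects.items():
            total = dw_null + eff.adherence * (eff.dw_change + eff.dw_change_eps)
            if not (0.0 <= total <= 1.0):
                report.append(
                    Violation(f"effects.{key}.dw_change", "drives total DW outside [0, 1]")
                )

    for path_key, spec in ps.distributions.items():
        base = f"distributions.{path_key}"
        if spec.kind not in _DIST_KINDS:
            report.append(Violation(base, f"unknown kind {spec.kind!r}"))
            continue
        missing = [p for p in _DIST_PARAM_NAMES[spec.kind] if p not in spec.params]
        if missing:
            report.append(Violation(base, f"missing parameter(s) {missing}"))
        leaf = path_key.rsplit(".", 1)[-1]
        if spec.kind == "beta" and leaf not in _FRACTION_FIELDS:
            report.append(Violation(base, "beta reserved for [0,1] quantities"))
        if spec.kind in ("gamma", "lognormal") and leaf in _SIGNED_FIELDS:
            report.append(
                Violation(base, f"{spec.kind} reserved for nonnegative quantities")
            )
        try:
            resolve_path(ps, path_key)
        except (AttributeError, KeyError):
            report.append(Violation(base, "path does not resolve in parameter set"))
    return report


# -- parameter-path plumbing --------------------------------------------


def _walk(ps: ParameterSet, path: str):
    parts = path.split(".")
    obj: Any = ps
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj, parts[-1]


def resolve_path(ps: ParameterSet, path: str) -> float:
    """Fetch a scalar parameter by dotted path, e.g. ``effects.risperidone.dw_change``."""
    obj, leaf = _walk(ps, path)
    return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)


def set_by_path(ps: ParameterSet, path: str, value: float) -> None:
    obj, leaf = _walk(ps, path)
    if isinstance(obj, dict):
        obj[leaf] = value
    else:
        setattr(obj, leaf, value)
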