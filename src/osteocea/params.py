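"""Model parameters for the fracture-prevention cost-effectiveness model.

Every quantity needed by the simulation lives in a single :class:`ParameterSet`:
drug efficacy and adherence/persistence schedules, age-banded fracture
incidence, excess-mortality parameters, health-state utilities, costs (in 2020
Japanese yen), and economic settings (discounting, willingness-to-pay,
currency conversion).  :func:`default_parameters` builds the base case.

For sensitivity analyses every varied parameter is addressable through a
stable string identifier (e.g. ``"teriparatide.rr_vert"``) in
:data:`PARAM_REGISTRY`, which records the deterministic range and the
probabilistic distribution alongside a setter that applies a drawn value to a
``ParameterSet``.

Beta and gamma distributions for probabilistic sensitivity analysis are
specified only through their 95% interval, so :func:`fit_beta_from_ci` /
:func:`fit_gamma_from_ci` recover shape parameters whose 2.5% and 97.5%
quantiles reproduce the printed bounds.
"""

from __future__ import annotations

import bisect
import copy
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AgeBandTable",
    "DrugParams",
    "FractureEpidemiology",
    "ExcessMortalityParams",
    "UtilityModel",
    "CostModel",
    "EconSettings",
    "ParameterSet",
    "DistributionSpec",
    "ParamSpec",
    "PARAM_REGISTRY",
    "default_parameters",
    "fit_beta_from_ci",
    "fit_gamma_from_ci",
    "sample_parameter",
    "apply_overrides",
]


# ---------------------------------------------------------------------------
# Age-banded lookup


@dataclass
class AgeBandTable:
    """Step-function lookup keyed on the lower bound of each age band."""

    lower_bounds: list[int]
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.lower_bounds) != len(self.values):
            raise ValueError("lower_bounds and values must have equal length")
        if any(b >= a for a, b in zip(self.lower_bounds[1:], self.lower_bounds)):
            raise ValueError("lower_bounds must be strictly increasing")

    def lookup(self, age: float) -> float:
        if age < self.lower_bounds[0]:
            raise ValueError(f"age {age} below first band ({self.lower_bounds[0]})")
        i = bisect.bisect_right(self.lower_bounds, age) - 1
        return self.values[i]

    def scaled(self, factor: float) -> "AgeBandTable":
        return AgeBandTable(list(self.lower_bounds), [v * factor for v in self.values])


# ---------------------------------------------------------------------------
# Parameter blocks


@dataclass
class DrugParams:
    """Efficacy, adherence/persistence schedule, and costs for one drug.

    Relative risks are trial (full-adherence) values versus no treatment.
    Anchor points give the printed schedule values; the treatment module
    interpolates between them (linearly for adherence, geometrically for
    cumulative persistence).  ``adherence_scale`` / ``persistence_scale`` are
    multiplicative knobs used by the sensitivity analyses (values above 1 are
    capped at 1 at evaluation time).
    """

    name: str
    rr_hip: float
    rr_vert: float
    duration_years: int          # full treatment period the offset rule is scaled to
    offset_years: float          # offset length after completing duration_years
    adherence_anchor_points: list[tuple[int, float]]
    persistence_anchor_points: list[tuple[int, float]]
    annual_drug_cost: float
    prescription_charge: float
    first_visit_cost: float
    subsequent_visit_cost: float
    adherence_scale: float = 1.0
    persistence_scale: float = 1.0

    def validate(self) -> None:
        for rr in (self.rr_hip, self.rr_vert):
            if not 0 < rr <= 1:
                raise ValueError(f"{self.name}: relative risk {rr} outside (0, 1]")
        for _, a in self.adherence_anchor_points:
            if not 0 < a <= 1:
                raise ValueError(f"{self.name}: adherence {a} outside (0, 1]")
        pers = [p for _, p in self.persistence_anchor_points]
        if any(not 0 <= p <= 1 for p in pers):
            raise ValueError(f"{self.name}: persistence outside [0, 1]")
        if any(b > a for a, b in zip(pers, pers[1:])):
            raise ValueError(f"{self.name}: cumulative persistence must be non-increasing")
        for c in (self.annual_drug_cost, self.prescription_charge,
                  self.first_visit_cost, self.subsequent_visit_cost):
            if c < 0:
                raise ValueError(f"{self.name}: negative cost {c}")


@dataclass
class FractureEpidemiology:
    """Annual fracture incidence (per 100,000 person-years, untreated) and
    the relative risks conferred by the cohort's prior vertebral fracture."""

    hip_rates: AgeBandTable
    vert_rates: AgeBandTable
    rr_prior_vf_hip: float = 2.3
    rr_prior_vf_vert: float = 4.4
    max_hip_fractures: int = 2

    def validate(self) -> None:
        if self.rr_prior_vf_hip < 1 or self.rr_prior_vf_vert < 1:
            raise ValueError("prior-fracture relative risks must be >= 1")
        for table in (self.hip_rates, self.vert_rates):
            if any(v < 0 for v in table.values):
                raise ValueError("incidence rates must be >= 0")


@dataclass
class ExcessMortalityParams:
    """Excess mortality after hip fracture: relative hazards in the fracture
    year and lifelong thereafter, attenuated by the attributable fraction.
    ``attributable_vert`` is 0 in the base case (switched on in the
    vertebral-excess-mortality scenario)."""

    rh_hip_year1: float = 2.87
    rh_hip_later: float = 1.73
    attributable_hip: float = 0.25
    attributable_vert: float = 0.0

    def validate(self) -> None:
        if self.rh_hip_year1 < 1 or self.rh_hip_later < 1:
            raise ValueError("relative hazards must be >= 1")
        for a in (self.attributable_hip, self.attributable_vert):
            if not 0 <= a <= 1:
                raise ValueError("attributable fractions must lie in [0, 1]")


@dataclass
class UtilityModel:
    """Baseline EQ-5D utility by age band and multiplicative fracture
    disutilities (first year after the fracture vs lifelong thereafter)."""

    baseline: AgeBandTable
    hip_mult_year1: float = 0.776
    hip_mult_later: float = 0.855
    vert_mult_year1: float = 0.724
    vert_mult_later: float = 0.868
    baseline_scale: float = 1.0   # PSA knob; applied with a cap at 1.0

    def validate(self) -> None:
        mults = (self.hip_mult_year1, self.hip_mult_later,
                 self.vert_mult_year1, self.vert_mult_later)
        if any(not 0 < m <= 1 for m in mults):
            raise ValueError("disutility multipliers must lie in (0, 1]")
        if any(not 0 < u <= 1 for u in self.baseline.values):
            raise ValueError("baseline utilities must lie in (0, 1]")


@dataclass
class CostModel:
    """Per-event and per-state costs in yen. Fracture treatment costs are
    healthcare-sector; long-term care (LTC) costs are the non-healthcare
    sector."""

    hip_medical_cost: float = 1_726_000.0
    vert_first_cost: float = 420_000.0
    vert_subsequent_cost: float = 842_000.0
    ltc_post_hip: float = 876_000.0
    ltc_post_vert: float = 213_000.0
    blood_test_cost: float = 2_900.0
    blood_tests_per_year: int = 2
    dxa_cost: float = 4_500.0
    dxa_years: tuple[int, ...] = (2, 5, 10)
    visits_per_year: int = 4

    def validate(self) -> None:
        for c in (self.hip_medical_cost, self.vert_first_cost, self.vert_subsequent_cost,
                  self.ltc_post_hip, self.ltc_post_vert, self.blood_test_cost, self.dxa_cost):
            if c < 0:
                raise ValueError("costs must be >= 0")


@dataclass
class EconSettings:
    discount_cost: float = 0.02
    discount_qaly: float = 0.02
    wtp_thresholds: tuple[float, ...] = (5_000_000.0, 10_000_000.0)
    yen_per_usd: float = 105.0
    horizon_age: int = 105
    perspective: str = "healthcare_plus_ltc"   # or "healthcare_only"

    def validate(self) -> None:
        for r in (self.discount_cost, self.discount_qaly):
            if not 0 <= r <= 0.10:
                raise ValueError(f"discount rate {r} outside [0, 0.10]")
        if self.perspective not in ("healthcare_plus_ltc", "healthcare_only"):
            raise ValueError(f"unknown perspective {self.perspective!r}")


@dataclass
class ParameterSet:
    drugs: dict[str, DrugParams]
    epidemiology: FractureEpidemiology
    mortality_extras: ExcessMortalityParams
    utilities: UtilityModel
    costs: CostModel
    econ: EconSettings

    def validate(self) -> None:
        for d in self.drugs.values():
            d.validate()
        self.epidemiology.validate()
        self.mortality_extras.validate()
        self.utilities.validate()
        self.costs.validate()
        self.econ.validate()

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_json(self) -> str:
        from dataclasses import asdict
        return json.dumps(asdict(self), indent=2, default=list)


# ---------------------------------------------------------------------------
# Base case


def default_parameters() -> ParameterSet:
    """Base-case parameter set.

    Adherence schedules use the study values behind the rounded headline
    rates: teriparatide 70.2% (year 1) and 67.8% (year 2); alendronate 70.6%
    (year 1) declining linearly to 60.9% (year 5), constant thereafter.
    Cumulative persistence anchors: teriparatide 68.0% / 51.6% at the end of
    years 1 / 2; alendronate 55% at year 1 and 10% at year 7 with no further
    dropout through year 10.
    """
    teriparatide = DrugParams(
        name="teriparatide",
        rr_hip=0.35,
        rr_vert=0.23,
        duration_years=2,
        offset_years=2.0,
        adherence_anchor_points=[(1, 0.702), (2, 0.678)],
        persistence_anchor_points=[(1, 0.68), (2, 0.516)],
        annual_drug_cost=333_400.0,
        prescription_charge=1_100.0,
        first_visit_cost=18_300.0,
        subsequent_visit_cost=9_400.0,
    )
    alendronate = DrugParams(
        name="alendronate",
        rr_hip=0.64,
        rr_vert=0.50,
        duration_years=10,
        offset_years=10.0,
        adherence_anchor_points=[(1, 0.706), (5, 0.609)],
        persistence_anchor_points=[(1, 0.55), (7, 0.10)],
        annual_drug_cost=8_700.0,
        prescription_charge=1_700.0,
        first_visit_cost=3_600.0,
        subsequent_visit_cost=1_900.0,
    )
    epi = FractureEpidemiology(
        hip_rates=AgeBandTable(
            [70, 75, 80, 85, 90, 95, 100],
            [158.1, 362.2, 851.1, 1580.2, 2466.0, 2961.7, 2471.0],
        ),
        vert_rates=AgeBandTable(
            [70, 75, 80, 85, 90, 95, 100],
            [514.0, 1106.0, 2034.0, 2331.0, 3638.0, 4369.0, 3645.0],
        ),
    )
    utilities = UtilityModel(
        baseline=AgeBandTable([65, 70, 75, 80, 85],
                              [0.862, 0.810, 0.771, 0.769, 0.684]),
    )
    ps = ParameterSet(
        drugs={"teriparatide": teriparatide, "alendronate": alendronate},
        epidemiology=epi,
        mortality_extras=ExcessMortalityParams(),
        utilities=utilities,
        costs=CostModel(),
        econ=EconSettings(),
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Distributions


@dataclass(frozen=True)
class DistributionSpec:
    """Probabilistic specification for one parameter.

    ``beta_from_ci`` / ``gamma_from_ci`` interpret (lo, hi) as the 2.5% and
    97.5% quantiles; ``triangular`` uses base as the mode and (lo, hi) as the
    support; ``fixed`` always returns base.
    """

    kind: str
    base: float
    lo: float = float("nan")
    hi: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("beta_from_ci", "gamma_from_ci", "triangular", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind != "fixed":
            if not self.lo <= self.base <= self.hi:
                raise ValueError(f"need lo <= base <= hi, got {self.lo}, {self.base}, {self.hi}")
        if self.kind == "beta_from_ci" and not (0 < self.lo < self.hi < 1):
            raise ValueError("beta_from_ci requires 0 < lo < hi < 1")
        if self.kind == "gamma_from_ci" and not (0 < self.lo < self.hi):
            raise ValueError("gamma_from_ci requires 0 < lo < hi")


@lru_cache(maxsize=None)
def fit_beta_from_ci(lo: float, hi: float) -> tuple[float, float]:
    """Shape parameters (a, b) of a beta distribution whose 2.5% / 97.5%
    quantiles equal ``lo`` / ``hi``.

    Solved as a two-parameter root find in log-shape space, seeded from the
    normal approximation (mean = midpoint, sd = width/3.92).
    """
    if not (0 < lo < hi < 1):
        raise ValueError(f"beta CI bounds must satisfy 0 < lo < hi < 1, got ({lo}, {hi})")
    m = 0.5 * (lo + hi)
    sd = (hi - lo) / 3.92
    nu = max(m * (1 - m) / sd**2 - 1, 1e-3)
    x0 = np.log([m * nu, (1 - m) * nu])

    def resid(logab: np.ndarray) -> np.ndarray:
        a, b = np.exp(logab)
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return np.array([q[0] - lo, q[1] - hi])

    sol = optimize.root(resid, x0, method="hybr", tol=1e-13)
    a, b = np.exp(sol.x)
    q = stats.beta.ppf([0.025, 0.975], a, b)
    if abs(q[0] - lo) > 1e-6 * lo or abs(q[1] - hi) > 1e-6 * hi:
        raise RuntimeError(f"beta CI fit failed for ({lo}, {hi}): quantiles {q}")
    return float(a), float(b)


@lru_cache(maxsize=None)
def fit_gamma_from_ci(lo: float, hi: float) -> tuple[float, float]:
    """Shape and scale of a gamma distribution whose 2.5% / 97.5% quantiles
    equal ``lo`` / ``hi``.

    The quantile ratio q97.5/q2.5 is scale-free, so the shape is found by a
    1-D bracketed root find and the scale follows directly.
    """
    if not (0 < lo < hi):
        raise ValueError(f"gamma CI bounds must satisfy 0 < lo < hi, got ({lo}, {hi})")
    target = hi / lo

    def ratio(logk: float) -> float:
        k = np.exp(logk)
        q = stats.gamma.ppf([0.025, 0.975], k)
        if q[0] <= 0:   # lower quantile underflows for tiny shapes
            return float("inf")
        return q[1] / q[0] - target

    # ratio is decreasing in k: large shape -> concentrated -> ratio -> 1
    # (upper bracket large enough for near-degenerate intervals)
    a, b = -10.0, 60.0
    logk = optimize.brentq(ratio, a, b, xtol=1e-14, rtol=8.9e-16)
    k = float(np.exp(logk))
    scale = lo / stats.gamma.ppf(0.025, k)
    q = stats.gamma.ppf([0.025, 0.975], k, scale=scale)
    if abs(q[0] - lo) > 1e-6 * lo or abs(q[1] - hi) > 1e-6 * hi:
        raise RuntimeError(f"gamma CI fit failed for ({lo}, {hi}): quantiles {q}")
    return k, float(scale)


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a :class:`DistributionSpec`."""
    if spec.kind == "fixed":
        return spec.base
    if spec.kind == "triangular":
        if spec.lo == spec.hi:
            return spec.base
        return float(rng.triangular(spec.lo, spec.base, spec.hi))
    if spec.kind == "beta_from_ci":
        a, b = fit_beta_from_ci(spec.lo, spec.hi)
        return float(rng.beta(a, b))
    if spec.kind == "gamma_from_ci":
        k, scale = fit_gamma_from_ci(spec.lo, spec.hi)
        return float(rng.gamma(k, scale))
    raise AssertionError(spec.kind)


# ---------------------------------------------------------------------------
# Parameter registry for sensitivity analyses


@dataclass(frozen=True)
class ParamSpec:
    """One sensitivity-addressable parameter: identifier, base value,
    deterministic range (if the parameter has one), probabilistic
    distribution (if sampled in the PSA), and a setter."""

    param_id: str
    base: float
    apply: Callable[[ParameterSet, float], None]
    dsa_range: tuple[float, float] | None = None
    psa: DistributionSpec | None = None


def _set_drug(attr: str):
    def setter(drug: str):
        def apply(ps: ParameterSet, v: float) -> None:
            setattr(ps.drugs[drug], attr, v)
        return apply
    return setter


def _adherence_scale(drug: str, base_year1: float):
    # Per the ratio rule for adherence bounds: the year-1 bound divided by the
    # year-1 base value rescales the whole schedule (capped at 1 downstream).
    def apply(ps: ParameterSet, v: float) -> None:
        ps.drugs[drug].adherence_scale = v / base_year1
    return apply


def _persistence_scale(drug: str):
    def apply(ps: ParameterSet, v: float) -> None:
        ps.drugs[drug].persistence_scale = v
    return apply


def _fracture_cost_scale(ps: ParameterSet, v: float) -> None:
    c = ps.costs
    c.hip_medical_cost = 1_726_000.0 * v
    c.vert_first_cost = 420_000.0 * v
    c.vert_subsequent_cost = 842_000.0 * v


def _ltc_cost_scale(ps: ParameterSet, v: float) -> None:
    ps.costs.ltc_post_hip = 876_000.0 * v
    ps.costs.ltc_post_vert = 213_000.0 * v


def _hip_incidence_scale(ps: ParameterSet, v: float) -> None:
    ps.epidemiology.hip_rates = default_parameters().epidemiology.hip_rates.scaled(v)


def _vert_incidence_scale(ps: ParameterSet, v: float) -> None:
    ps.epidemiology.vert_rates = default_parameters().epidemiology.vert_rates.scaled(v)


def _discount_both(ps: ParameterSet, v: float) -> None:
    ps.econ.discount_cost = v
    ps.econ.discount_qaly = v


def _simple(path: str):
    """Setter for a dotted attribute path on the ParameterSet."""
    def apply(ps: ParameterSet, v: float) -> None:
        obj = ps
        *head, last = path.split(".")
        for part in head:
            obj = getattr(obj, part)
        setattr(obj, last, v)
    return apply


def _build_registry() -> dict[str, ParamSpec]:
    tri = lambda base, lo, hi: DistributionSpec("triangular", base, lo, hi)
    beta = lambda base, lo, hi: DistributionSpec("beta_from_ci", base, lo, hi)
    gamma = lambda base, lo, hi: DistributionSpec("gamma_from_ci", base, lo, hi)
    specs = [
        # Drug efficacy (trial relative risks); 95% CIs from meta-analysis
        ParamSpec("teriparatide.rr_hip", 0.35, _set_drug("rr_hip")("teriparatide"),
                  (0.15, 0.73), beta(0.35, 0.15, 0.73)),
        ParamSpec("teriparatide.rr_vert", 0.23, _set_drug("rr_vert")("teriparatide"),
                  (0.16, 0.32), beta(0.23, 0.16, 0.32)),
        ParamSpec("alendronate.rr_hip", 0.64, _set_drug("rr_hip")("alendronate"),
                  (0.45, 0.88), beta(0.64, 0.45, 0.88)),
        ParamSpec("alendronate.rr_vert", 0.50, _set_drug("rr_vert")("alendronate"),
                  (0.40, 0.64), beta(0.50, 0.40, 0.64)),
        # First-year adherence; bounds rescale the full schedule
        ParamSpec("teriparatide.adherence_year1", 0.702,
                  _adherence_scale("teriparatide", 0.702),
                  (0.6, 0.8), tri(0.702, 0.6, 0.8)),
        ParamSpec("alendronate.adherence_year1", 0.706,
                  _adherence_scale("alendronate", 0.706),
                  (0.62, 0.8), tri(0.706, 0.62, 0.8)),
        # Persistence: +-15% on the annual continuation rates
        ParamSpec("teriparatide.persistence_annual_scale", 1.0,
                  _persistence_scale("teriparatide"),
                  (0.85, 1.15), tri(1.0, 0.85, 1.15)),
        ParamSpec("alendronate.persistence_annual_scale", 1.0,
                  _persistence_scale("alendronate"),
                  (0.85, 1.15), tri(1.0, 0.85, 1.15)),
        # Fracture medical costs and LTC costs: grouped +-50% multipliers
        ParamSpec("costs.fracture_medical_scale", 1.0, _fracture_cost_scale,
                  (0.5, 1.5), tri(1.0, 0.5, 1.5)),
        ParamSpec("costs.ltc_scale", 1.0, _ltc_cost_scale,
                  (0.5, 1.5), tri(1.0, 0.5, 1.5)),
        # Incidence: +-50% deterministic; tighter probabilistic ranges
        ParamSpec("epidemiology.hip_incidence_scale", 1.0, _hip_incidence_scale,
                  (0.5, 1.5), tri(1.0, 0.9, 1.1)),
        ParamSpec("epidemiology.vert_incidence_scale", 1.0, _vert_incidence_scale,
                  (0.5, 1.5), tri(1.0, 0.75, 1.25)),
        # PSA-only parameters
        ParamSpec("utilities.baseline_scale", 1.0, _simple("utilities.baseline_scale"),
                  None, tri(1.0, 0.85, 1.15)),
        ParamSpec("utilities.hip_mult_year1", 0.776, _simple("utilities.hip_mult_year1"),
                  None, beta(0.776, 0.720, 0.844)),
        ParamSpec("utilities.hip_mult_later", 0.855, _simple("utilities.hip_mult_later"),
                  None, beta(0.855, 0.800, 0.909)),
        ParamSpec("utilities.vert_mult_year1", 0.724, _simple("utilities.vert_mult_year1"),
                  None, beta(0.724, 0.667, 0.779)),
        ParamSpec("utilities.vert_mult_later", 0.868, _simple("utilities.vert_mult_later"),
                  None, beta(0.868, 0.827, 0.922)),
        ParamSpec("epidemiology.rr_prior_vf_hip", 2.3, _simple("epidemiology.rr_prior_vf_hip"),
                  None, gamma(2.3, 2.0, 2.8)),
        ParamSpec("epidemiology.rr_prior_vf_vert", 4.4, _simple("epidemiology.rr_prior_vf_vert"),
                  None, gamma(4.4, 3.6, 5.4)),
        ParamSpec("mortality.rh_hip_year1", 2.87, _simple("mortality_extras.rh_hip_year1"),
                  None, gamma(2.87, 2.52, 3.27)),
        ParamSpec("mortality.rh_hip_later", 1.73, _simple("mortality_extras.rh_hip_later"),
                  None, gamma(1.73, 1.56, 1.90)),
        ParamSpec("mortality.attributable_hip", 0.25, _simple("mortality_extras.attributable_hip"),
                  None, tri(0.25, 0.0, 0.5)),
        ParamSpec("econ.discount_rate", 0.02, _discount_both,
                  None, tri(0.02, 0.0, 0.04)),
        # Override-only knobs (no printed range; not part of DSA/PSA loops)
        ParamSpec("teriparatide.annual_cost", 333_400.0,
                  _set_drug("annual_drug_cost")("teriparatide")),
        ParamSpec("teriparatide.offset_years", 2.0,
                  _set_drug("offset_years")("teriparatide")),
        ParamSpec("mortality.attributable_vert", 0.0,
                  _simple("mortality_extras.attributable_vert")),
    ]
    return {s.param_id: s for s in specs}


PARAM_REGISTRY: dict[str, ParamSpec] = _build_registry()

#: identifiers varied in the one-way deterministic sensitivity analysis
DSA_PARAM_IDS: list[str] = [
    pid for pid, s in PARAM_REGISTRY.items() if s.dsa_range is not None
]

#: identifiers sampled in the probabilistic sensitivity analysis
PSA_PARAM_IDS: list[str] = [
    pid for pid, s in PARAM_REGISTRY.items() if s.psa is not None
]


def apply_overrides(params: ParameterSet, overrides: dict[str, float]) -> ParameterSet:
    """Return a copy of ``params`` with registry-identified overrides applied.

    Unknown identifiers raise ``KeyError`` listing the valid ones.
    """
    out = params.copy()
    for key, value in overrides.items():
        if key not in PARAM_REGISTRY:
            raise KeyError(
                f"unknown parameter identifier {key!r}; valid identifiers: "
                + ", ".join(sorted(PARAM_REGISTRY))
            )
        PARAM_REGISTRY[key].apply(out, float(value))
    out.validate()
    return out
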