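"""Microsimulation engine: annual-cycle individual trajectories and cohorts.

One woman at a time is simulated from her starting age until death or the
horizon age (105).  Each cycle:

1. treatment continuation is sampled (while on a drug);
2. effective relative-risk multipliers are computed (on-treatment, offset,
   or untreated);
3. at most one fracture is sampled (hip takes precedence), then death;
4. the cycle's costs (by payer sector) and utility are written to a ledger.

Events are end-of-cycle: all of the cycle's costs are booked even if the
woman dies that cycle, but a death cycle contributes zero utility (no
half-cycle correction).  Discounting applies (1+r)^(-t) with the first
treatment year undiscounted.

Costs while on a drug comprise the drug itself (annual cost x adherence),
the yearly prescription charge, quarterly physician visits (the drug's first
visit at the initiation fee), twice-yearly blood tests, and a bone-density
(DXA) scan at the end of treatment years 2, 5, and 10.  A woman who
discontinues during a year is charged one 3-month supply and a single visit,
and receives no fracture protection that cycle.  Fracture treatment costs
are booked in the fracture cycle; long-term-care costs run from the first
state-defining fracture (half in that first cycle) until death, at the
post-hip rate when any hip fracture has occurred, else the post-vertebral
rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lifetables import LifeTable
from .natural_history import FractureHistory, sample_cycle_events
from .params import ParameterSet
from .treatment import (
    OffsetState,
    StrategySpec,
    adherence,
    annual_continuation_prob,
    effective_rr,
    get_strategy,
    offset_length,
    offset_rr,
)

__all__ = [
    "CycleLedger",
    "IndividualState",
    "CohortResult",
    "cycle_utility",
    "simulate_individual",
    "run_cohort",
    "validate_no_intervention",
]


@dataclass(slots=True)
class CycleLedger:
    """Undiscounted record of one simulated year."""

    cycle_index: int
    drug_cost: float = 0.0
    visit_cost: float = 0.0
    test_cost: float = 0.0
    fracture_medical_cost: float = 0.0
    ltc_cost: float = 0.0
    utility: float = 0.0

    @property
    def healthcare_cost(self) -> float:
        return (self.drug_cost + self.visit_cost + self.test_cost
                + self.fracture_medical_cost)

    @property
    def total_cost(self) -> float:
        return self.healthcare_cost + self.ltc_cost


@dataclass(slots=True)
class IndividualState:
    """One woman's evolving state."""

    age: int
    alive: bool = True
    history: FractureHistory = field(default_factory=FractureHistory)
    phase: str = "off"            # on_<drug>, offset, off
    phase_index: int = 0          # index into the strategy's phases while on-drug
    phase_year: int = 1           # 1-based year within the current drug phase
    strategy_year: int = 1        # 1-based year since therapy initiation
    offset: OffsetState | None = None
    had_first_visit: set = field(default_factory=set)


def cycle_utility(
    age: int,
    hip_this_cycle: bool,
    vert_this_cycle: bool,
    history: FractureHistory,
    died: bool,
    params: ParameterSet,
) -> float:
    """QALY weight for one cycle: age-band baseline utility times the
    applicable fracture multipliers (first-year multiplier in a fracture
    cycle, the lifelong one in every later cycle; hip and vertebral combine
    multiplicatively). A death cycle contributes zero."""
    if died:
        return 0.0
    u = params.utilities.baseline.lookup(age)
    u = min(u * params.utilities.baseline_scale, 1.0)
    if hip_this_cycle:
        u *= params.utilities.hip_mult_year1
    elif history.n_hip > 0:
        u *= params.utilities.hip_mult_later
    if vert_this_cycle:
        u *= params.utilities.vert_mult_year1
    elif history.n_vert > 0:
        u *= params.utilities.vert_mult_later
    return u


def simulate_individual(
    strategy: StrategySpec | str,
    start_age: int,
    params: ParameterSet,
    life_table: LifeTable,
    rng: np.random.Generator,
) -> list[CycleLedger]:
    """Simulate one woman; returns her per-cycle ledger."""
    ledgers, _ = _simulate(strategy, start_age, params, life_table, rng)
    return ledgers


def _simulate(
    strategy: StrategySpec | str,
    start_age: int,
    params: ParameterSet,
    life_table: LifeTable,
    rng: np.random.Generator,
) -> tuple[list[CycleLedger], IndividualState]:
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    horizon = params.econ.horizon_age
    if start_age >= horizon:
        raise ValueError(f"start_age {start_age} must be below horizon {horizon}")
    life_table.require_coverage(start_age, horizon - 1)

    epi = params.epidemiology
    mort = params.mortality_extras
    costs = params.costs
    drugs = params.drugs

    state = IndividualState(age=start_age)
    if strategy.phases:
        state.phase = "on_" + strategy.phases[0].drug
        state.phase_index = 0

    n_cycles = horizon - start_age
    # fixed draw layout (continuation, hip, vert, death) per cycle keeps
    # random-number streams aligned across strategies and sweep points
    u = rng.random((n_cycles, 4))

    ledgers: list[CycleLedger] = []
    for t in range(n_cycles):
        age = state.age
        hist = state.history
        led = CycleLedger(cycle_index=t)

        on_drug = state.phase.startswith("on_")
        persisted = False
        discontinued = False
        drug = None
        if on_drug:
            drug = drugs[strategy.phases[state.phase_index].drug]
            persisted = u[t, 0] < annual_continuation_prob(drug, state.phase_year)
            discontinued = not persisted

        # --- treatment multipliers -------------------------------------
        if on_drug and persisted:
            mult_hip = effective_rr(drug, "hip", state.phase_year)
            mult_vert = effective_rr(drug, "vert", state.phase_year)
        elif state.phase == "offset":
            off = state.offset
            mult_hip = offset_rr(off.rr_stop_hip, off.offset_len, off.years_since_stop)
            mult_vert = offset_rr(off.rr_stop_vert, off.offset_len, off.years_since_stop)
        else:
            mult_hip = mult_vert = 1.0

        # --- events -----------------------------------------------------
        ev = sample_cycle_events(hist, age, mult_hip, mult_vert, epi, mort,
                                 life_table, u[t, 1], u[t, 2], u[t, 3])

        # --- treatment costs ---------------------------------------------
        if on_drug:
            if persisted:
                led.drug_cost = drug.annual_drug_cost * adherence(drug, state.phase_year)
                led.drug_cost += drug.prescription_charge
                if drug.name in state.had_first_visit:
                    led.visit_cost = costs.visits_per_year * drug.subsequent_visit_cost
                else:
                    led.visit_cost = (drug.first_visit_cost
                                      + (costs.visits_per_year - 1) * drug.subsequent_visit_cost)
                    state.had_first_visit.add(drug.name)
                led.test_cost = costs.blood_tests_per_year * costs.blood_test_cost
                if state.strategy_year in costs.dxa_years:
                    led.test_cost += costs.dxa_cost
            else:
                led.drug_cost = drug.annual_drug_cost / 4.0   # one 3-month supply
                if drug.name in state.had_first_visit:
                    led.visit_cost = drug.subsequent_visit_cost
                else:
                    led.visit_cost = drug.first_visit_cost
                    state.had_first_visit.add(drug.name)

        # --- fracture and long-term-care costs ----------------------------
        if ev.hip:
            led.fracture_medical_cost = costs.hip_medical_cost
        elif ev.vert:
            led.fracture_medical_cost = (costs.vert_first_cost if ev.first_vert
                                         else costs.vert_subsequent_cost)
        if hist.n_hip > 0:
            led.ltc_cost = costs.ltc_post_hip * (0.5 if ev.first_hip else 1.0)
        elif hist.n_vert > 0:
            led.ltc_cost = costs.ltc_post_vert * (0.5 if ev.first_vert else 1.0)

        # --- utility -------------------------------------------------------
        led.utility = cycle_utility(age, ev.hip, ev.vert, hist, ev.died, params)

        ledgers.append(led)
        if ev.died:
            state.alive = False
            break

        # --- phase transitions --------------------------------------------
        if on_drug:
            phase_dur = strategy.phases[state.phase_index].duration
            if discontinued:
                years_taken = state.phase_year - 1
                _enter_offset(state, drug, years_taken)
            elif state.phase_year == phase_dur:
                if state.phase_index + 1 < len(strategy.phases):
                    state.phase_index += 1
                    state.phase = "on_" + strategy.phases[state.phase_index].drug
                    state.phase_year = 1
                else:
                    _enter_offset(state, drug, phase_dur)
            else:
                state.phase_year += 1
        elif state.phase == "offset":
            state.offset.years_since_stop += 1
            if state.offset.years_since_stop >= state.offset.offset_len:
                state.phase = "off"
                state.offset = None

        if on_drug:
            state.strategy_year += 1
        state.age += 1

    return ledgers, state


def _enter_offset(state: IndividualState, drug, years_taken: int) -> None:
    """Move to the offset phase after stopping ``drug`` with ``years_taken``
    completed years. The offset starts from the effective RR of the final
    persisted year; with no completed year it is vacuous."""
    if years_taken <= 0:
        state.phase = "off"
        state.offset = None
        return
    state.offset = OffsetState(
        drug=drug.name,
        years_taken=years_taken,
        offset_len=offset_length(drug, years_taken),
        rr_stop_hip=effective_rr(drug, "hip", years_taken),
        rr_stop_vert=effective_rr(drug, "vert", years_taken),
        years_since_stop=1.0,   # evaluated next cycle
    )
    state.phase = "offset"


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortResult:
    """Discounted per-strategy means over ``n`` simulated women."""

    strategy: str
    start_age: int
    n: int
    mean_cost_healthcare: float
    mean_cost_ltc: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    lifetime_p_hip: float
    lifetime_p_vert: float
    p_dead_by_105: float

    def mean_cost(self, perspective: str = "healthcare_plus_ltc") -> float:
        if perspective == "healthcare_plus_ltc":
            return self.mean_cost_healthcare + self.mean_cost_ltc
        if perspective == "healthcare_only":
            return self.mean_cost_healthcare
        raise ValueError(f"unknown perspective {perspective!r}")


def run_cohort(
    strategy: str | StrategySpec,
    start_age: int,
    n: int,
    seed: int,
    params: ParameterSet,
    life_table: LifeTable,
) -> CohortResult:
    """Simulate ``n`` independent women and aggregate discounted outcomes.

    Each woman gets her own deterministic random stream derived from
    (seed, index), so results are reproducible and two strategies run with
    the same seed share random numbers woman-for-woman and cycle-for-cycle
    (common random numbers)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    rc = params.econ.discount_cost
    rq = params.econ.discount_qaly
    horizon = params.econ.horizon_age
    disc_c = np.power(1.0 + rc, -np.arange(horizon - start_age))
    disc_q = np.power(1.0 + rq, -np.arange(horizon - start_age))

    sum_hc = sum_ltc = sum_q = 0.0
    sumsq_total = sumsq_q = 0.0
    n_hip_any = n_vert_any = n_dead = 0
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        ledgers, state = _simulate(strategy, start_age, params, life_table, rng)
        hc = ltc = q = 0.0
        for led in ledgers:
            t = led.cycle_index
            hc += led.healthcare_cost * disc_c[t]
            ltc += led.ltc_cost * disc_c[t]
            q += led.utility * disc_q[t]
        sum_hc += hc
        sum_ltc += ltc
        sum_q += q
        sumsq_total += (hc + ltc) ** 2
        sumsq_q += q ** 2
        if state.history.n_hip > 0:
            n_hip_any += 1
        if state.history.n_vert > 0:
            n_vert_any += 1
        if not state.alive:
            n_dead += 1

    mean_total = (sum_hc + sum_ltc) / n
    mean_q = sum_q / n
    var_total = max(sumsq_total / n - mean_total**2, 0.0) * n / max(n - 1, 1)
    var_q = max(sumsq_q / n - mean_q**2, 0.0) * n / max(n - 1, 1)
    return CohortResult(
        strategy=strategy.name,
        start_age=start_age,
        n=n,
        mean_cost_healthcare=sum_hc / n,
        mean_cost_ltc=sum_ltc / n,
        mean_qaly=mean_q,
        se_cost=math.sqrt(var_total / n),
        se_qaly=math.sqrt(var_q / n),
        lifetime_p_hip=n_hip_any / n,
        lifetime_p_vert=n_vert_any / n,
        p_dead_by_105=n_dead / n,
    )


def validate_no_intervention(
    start_age: int,
    n: int,
    seed: int,
    params: ParameterSet,
    life_table: LifeTable,
) -> dict[str, float]:
    """No-treatment validation arm: lifetime fracture probabilities and the
    probability of dying before the horizon age."""
    res = run_cohort("no_intervention", start_age, n, seed, params, life_table)
    return {
        "start_age": float(start_age),
        "n": float(n),
        "p_dead_by_105": res.p_dead_by_105,
        "lifetime_p_hip": res.lifetime_p_hip,
        "lifetime_p_vert": res.lifetime_p_vert,
    }
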