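"""Fracture and mortality transition probabilities, and per-cycle sampling.

Age-banded incidence rates (per 100,000 person-years) become per-cycle
probabilities through the rate-to-risk conversion p = 1 - exp(-r), after
multiplying the rate by the prior-vertebral-fracture relative risk (the whole
cohort has a prior vertebral fracture) and the current treatment multiplier.
At most one fracture can occur per cycle — hip is sampled first and takes
precedence — and no more than two hip fractures are allowed per lifetime.

Background mortality comes from the life table.  After a hip fracture the
death hazard is multiplied by m = 1 + f * (RH - 1), where RH is the relative
hazard (higher in the fracture year than thereafter) and f the fraction of
the observed excess mortality attributable to the fracture itself.  The same
construction applies to vertebral fractures only in the excess-vertebral-
mortality scenario (f_vert > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .lifetables import LifeTable
from .params import ExcessMortalityParams, FractureEpidemiology

__all__ = [
    "FractureHistory",
    "CycleEvents",
    "annual_fracture_prob",
    "mortality_multiplier",
    "annual_death_prob",
    "sample_cycle_events",
]


@dataclass
class FractureHistory:
    """Fracture history of one woman (baseline prior vertebral fracture is a
    cohort attribute, not counted here)."""

    n_hip: int = 0
    n_vert: int = 0
    years_since_hip: int | None = None   # 0 during the fracture cycle itself
    years_since_vert: int | None = None


@dataclass(frozen=True)
class CycleEvents:
    hip: bool
    vert: bool
    died: bool
    first_hip: bool
    first_vert: bool


def annual_fracture_prob(
    fracture_type: str,
    age: int,
    treatment_multiplier: float,
    history: FractureHistory,
    epi: FractureEpidemiology,
) -> float:
    """Per-cycle fracture probability at ``age`` under the given treatment
    multiplier. Returns 0 for hip once the lifetime maximum is reached."""
    if not 0 <= treatment_multiplier <= 1:
        raise ValueError(f"treatment multiplier {treatment_multiplier} outside [0, 1]")
    if fracture_type == "hip":
        if history.n_hip >= epi.max_hip_fractures:
            return 0.0
        rate = epi.hip_rates.lookup(age) * 1e-5 * epi.rr_prior_vf_hip
    elif fracture_type == "vert":
        rate = epi.vert_rates.lookup(age) * 1e-5 * epi.rr_prior_vf_vert
    else:
        raise ValueError(f"unknown fracture type {fracture_type!r}")
    return 1.0 - math.exp(-rate * treatment_multiplier)


def mortality_multiplier(history: FractureHistory, mort: ExcessMortalityParams) -> float:
    """Hazard multiplier from the fracture history.

    Uses the fracture-year relative hazard while ``years_since_* == 0`` (a
    recurrent fracture resets the clock) and the lifelong one thereafter;
    hip and vertebral (scenario only) contributions multiply on the hazard
    scale."""
    m = 1.0
    if history.n_hip > 0:
        rh = mort.rh_hip_year1 if history.years_since_hip == 0 else mort.rh_hip_later
        m *= 1.0 + mort.attributable_hip * (rh - 1.0)
    if mort.attributable_vert > 0 and history.n_vert > 0:
        rh = mort.rh_hip_year1 if history.years_since_vert == 0 else mort.rh_hip_later
        m *= 1.0 + mort.attributable_vert * (rh - 1.0)
    return m


def annual_death_prob(
    age: int,
    history: FractureHistory,
    life_table: LifeTable,
    mort: ExcessMortalityParams,
) -> float:
    """Per-cycle death probability: life-table qx converted to a hazard,
    multiplied by the excess-mortality factor, converted back."""
    qx = life_table.lookup(age)
    m = mortality_multiplier(history, mort)
    if m == 1.0:
        return qx
    h = -math.log(1.0 - qx) if qx < 1.0 else float("inf")
    return 1.0 - math.exp(-h * m)


def sample_cycle_events(
    history: FractureHistory,
    age: int,
    mult_hip: float,
    mult_vert: float,
    epi: FractureEpidemiology,
    mort: ExcessMortalityParams,
    life_table: LifeTable,
    u_hip: float,
    u_vert: float,
    u_death: float,
) -> CycleEvents:
    """Sample one cycle's events, mutating ``history`` in place.

    Order within the cycle: post-fracture clocks advance; the hip fracture is
    sampled, then the vertebral fracture conditional on no hip (one fracture
    per cycle, hip precedence); death is sampled last so the fracture-year
    excess hazard applies in the fracture cycle itself.  ``u_*`` are uniform
    [0, 1) draws, kept separate so callers can align random-number streams
    across strategies.
    """
    if history.years_since_hip is not None:
        history.years_since_hip += 1
    if history.years_since_vert is not None:
        history.years_since_vert += 1

    hip = u_hip < annual_fracture_prob("hip", age, mult_hip, history, epi)
    vert = False
    if not hip:
        vert = u_vert < annual_fracture_prob("vert", age, mult_vert, history, epi)

    first_hip = hip and history.n_hip == 0
    first_vert = vert and history.n_vert == 0
    if hip:
        history.n_hip += 1
        history.years_since_hip = 0
    if vert:
        history.n_vert += 1
        history.years_since_vert = 0

    died = u_death < annual_death_prob(age, history, life_table, mort)
    return CycleEvents(hip=hip, vert=vert, died=died,
                       first_hip=first_hip, first_vert=first_vert)
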