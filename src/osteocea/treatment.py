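"""Treatment schedules: persistence, adherence, and effective relative risks.

Community effectiveness is modelled as a linear attenuation of the trial
relative risk by adherence: a woman who persists through year ``y`` of a drug
with adherence ``a(y)`` faces fracture hazard multiplied by

    effective RR = 1 - a(y) * (1 - trial RR)

Persistence is a cumulative survival-on-therapy curve S(y) anchored at the
printed values and interpolated geometrically (constant annual continuation
ratio) between anchors; past the last anchor there is no further dropout.
Protection applies only if she persists to the end of the cycle.

After stopping (completion or discontinuation) the fracture risk returns
linearly to the untreated level over an offset period proportional to the
time actually spent on the drug.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import DrugParams, ParameterSet

__all__ = [
    "StrategyPhase",
    "StrategySpec",
    "STRATEGIES",
    "get_strategy",
    "cumulative_persistence",
    "annual_continuation_prob",
    "adherence",
    "effective_rr",
    "offset_length",
    "offset_rr",
    "OffsetState",
]


# ---------------------------------------------------------------------------
# Strategies


@dataclass(frozen=True)
class StrategyPhase:
    drug: str
    duration: int


@dataclass(frozen=True)
class StrategySpec:
    """Ordered treatment phases. A woman moves to the next phase only if she
    completes the current one; discontinuers exit to the offset phase."""

    name: str
    phases: tuple[StrategyPhase, ...]


STRATEGIES: dict[str, StrategySpec] = {
    "sequential": StrategySpec(
        "sequential",
        (StrategyPhase("teriparatide", 2), StrategyPhase("alendronate", 8)),
    ),
    "alendronate_mono": StrategySpec(
        "alendronate_mono", (StrategyPhase("alendronate", 10),)
    ),
    "no_intervention": StrategySpec("no_intervention", ()),
}


def get_strategy(name: str) -> StrategySpec:
    try:
        return STRATEGIES[name]
    except KeyError:
        raise KeyError(
            f"unknown strategy {name!r}; choose from {sorted(STRATEGIES)}"
        ) from None


# ---------------------------------------------------------------------------
# Persistence


def _base_continuation(drug: DrugParams, year: int) -> float:
    """Annual continuation probability S(y)/S(y-1) implied by the anchors,
    before any sensitivity scaling."""
    if year < 1:
        raise ValueError("year must be >= 1")
    anchors = drug.persistence_anchor_points
    prev_year, prev_s = 0, 1.0
    for y, s in anchors:
        if year <= y:
            # constant ratio between (prev_year, prev_s) and (y, s)
            if prev_s <= 0:
                return 1.0
            return (s / prev_s) ** (1.0 / (y - prev_year))
        prev_year, prev_s = y, s
    return 1.0  # no dropout beyond the last anchor (except for death)


def annual_continuation_prob(drug: DrugParams, year: int) -> float:
    """Per-cycle probability of persisting through year ``year`` of the drug,
    given persistence through year ``year - 1``.  Sensitivity scaling applies
    to this annual rate and is capped at 1."""
    c = _base_continuation(drug, year) * drug.persistence_scale
    return min(c, 1.0)


def cumulative_persistence(drug: DrugParams, year: int) -> float:
    """Probability of still being on the drug at the end of ``year``."""
    if year < 1:
        raise ValueError("year must be >= 1")
    s = 1.0
    for y in range(1, year + 1):
        s *= annual_continuation_prob(drug, y)
    return s


# ---------------------------------------------------------------------------
# Adherence


def adherence(drug: DrugParams, year: int) -> float:
    """Adherence rate during year ``year`` of the drug: piecewise-linear
    between anchors, flat beyond the last anchor, scaled and capped at 1."""
    if year < 1:
        raise ValueError("year must be >= 1")
    anchors = drug.adherence_anchor_points
    if year <= anchors[0][0]:
        a = anchors[0][1]
    elif year >= anchors[-1][0]:
        a = anchors[-1][1]
    else:
        for (y0, a0), (y1, a1) in zip(anchors, anchors[1:]):
            if y0 <= year <= y1:
                frac = (year - y0) / (y1 - y0)
                a = a0 + frac * (a1 - a0)
                break
    return min(a * drug.adherence_scale, 1.0)


# ---------------------------------------------------------------------------
# Effective relative risks


def effective_rr(drug: DrugParams, fracture_type: str, year: int) -> float:
    """Effective relative risk while persisting through year ``year``:
    1 - adherence * (1 - trial RR)."""
    trial_rr = drug.rr_hip if fracture_type == "hip" else drug.rr_vert
    return 1.0 - adherence(drug, year) * (1.0 - trial_rr)


def offset_length(drug: DrugParams, years_taken: float) -> float:
    """Offset period after stopping, proportional to the time on the drug:
    full offset x (years taken / full treatment duration)."""
    if years_taken < 0:
        raise ValueError("years_taken must be >= 0")
    frac = min(years_taken / drug.duration_years, 1.0)
    return drug.offset_years * frac


@dataclass
class OffsetState:
    """Post-treatment state: risk decays linearly from the last on-treatment
    effective RR back to 1 over ``offset_len`` years."""

    drug: str
    years_taken: float
    offset_len: float
    rr_stop_hip: float
    rr_stop_vert: float
    years_since_stop: float = 0.0


def offset_rr(rr_stop: float, offset_len: float, years_since_stop: float) -> float:
    """Relative risk ``years_since_stop`` years after stopping treatment."""
    if years_since_stop < 0:
        raise ValueError("years_since_stop must be >= 0")
    if offset_len <= 0 or years_since_stop >= offset_len:
        return 1.0
    return rr_stop + (1.0 - rr_stop) * (years_since_stop / offset_len)
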