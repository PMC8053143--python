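"""Health-economic comparisons: ICERs, dominance, net monetary benefit.

The incremental cost-effectiveness ratio (ICER) is the cost difference per
QALY gained between an intervention and its comparator.  Division is only
meaningful within a quadrant of the cost-effectiveness plane, so quadrant
cases are labelled explicitly:

* ``dominant``  — cheaper and at least as effective (always cost-effective);
* ``dominated`` — costlier and no more effective (never cost-effective);
* north-east (costlier, more effective): ICER compared with the
  willingness-to-pay (WTP) threshold;
* south-west (cheaper, less effective): the ICER is the saving per QALY
  forgone and the intervention is cost-effective when that saving exceeds
  the threshold.

All accounting is in yen; US-dollar figures are derived at reporting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import CohortResult
from .params import EconSettings

__all__ = ["ComparisonResult", "compare", "net_monetary_benefit", "yen_to_usd", "round_usd"]


def yen_to_usd(yen: float, econ: EconSettings) -> float:
    return yen / econ.yen_per_usd


def round_usd(usd: float, nearest: int = 10) -> float:
    """Round a dollar figure for display (nearest $10 for costs, nearest
    $100 for ICERs, matching common reporting convention)."""
    return round(usd / nearest) * nearest


@dataclass(frozen=True)
class ComparisonResult:
    intervention: str
    comparator: str
    start_age: int
    perspective: str
    delta_cost: float              # yen
    delta_qaly: float
    icer: float                    # yen/QALY; +-inf in degenerate cases
    label: str                     # "icer", "dominant", "dominated", "southwest"
    icer_usd: float
    cost_effective_at: dict[float, bool]

    @property
    def is_dominant(self) -> bool:
        return self.label == "dominant"

    @property
    def is_dominated(self) -> bool:
        return self.label == "dominated"


def compare(
    intervention: CohortResult,
    comparator: CohortResult,
    econ: EconSettings,
) -> ComparisonResult:
    """Pairwise comparison of two cohorts run at the same starting age."""
    if intervention.start_age != comparator.start_age:
        raise ValueError("cohorts must share a starting age")
    perspective = econ.perspective
    dc = intervention.mean_cost(perspective) - comparator.mean_cost(perspective)
    dq = intervention.mean_qaly - comparator.mean_qaly

    if dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
        label, icer = "dominant", -math.inf
        ce = {w: True for w in econ.wtp_thresholds}
    elif dc >= 0 and dq <= 0:
        # includes dq == 0 with dc > 0 (infinite ICER) and the null case
        label, icer = "dominated", math.inf
        ce = {w: False for w in econ.wtp_thresholds}
    elif dc > 0 and dq > 0:
        label, icer = "icer", dc / dq
        ce = {w: icer <= w for w in econ.wtp_thresholds}
    else:  # dc < 0, dq < 0: saving per QALY forgone
        label, icer = "southwest", dc / dq
        ce = {w: icer >= w for w in econ.wtp_thresholds}

    return ComparisonResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        start_age=intervention.start_age,
        perspective=perspective,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        label=label,
        icer_usd=icer / econ.yen_per_usd if math.isfinite(icer) else icer,
        cost_effective_at=ce,
    )


def net_monetary_benefit(
    result: CohortResult,
    wtp: float,
    econ: EconSettings,
) -> float:
    """NMB = WTP x mean QALYs - mean cost (perspective-appropriate, yen).
    For two strategies, the one with higher NMB at a threshold is the
    cost-effective choice at that threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.mean_qaly - result.mean_cost(econ.perspective)
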