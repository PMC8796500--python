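"""Incremental cost-effectiveness comparison of two strategies.

The incremental cost-effectiveness ratio is the ratio of the cost difference
to the effect difference between the intervention and the comparator.  A
strategy that is both cheaper and more effective dominates; the mirror case
is dominated; otherwise the ICER is compared against the willingness-to-pay
threshold, taken as a multiple of per-capita GDP.  Net monetary benefit
(NMB = effect x threshold - cost) is reported for both strategies and is the
authoritative statistic when the ICER falls in the south-west quadrant
(cheaper but less effective), where a raw ratio is not rankable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from mscea.markov_engine import ArmResult

VERDICTS = (
    "dominant",
    "dominated",
    "icer_below_threshold",
    "icer_above_threshold",
    "indeterminate",
)


class CEAError(ValueError):
    pass


@dataclass(frozen=True)
class Threshold:
    """Willingness-to-pay per QALY as a multiple of per-capita GDP."""

    gdp_per_capita: float
    multiplier: float
    value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0 or self.multiplier <= 0:
            raise CEAError("GDP and multiplier must be positive")
        object.__setattr__(self, "value", self.gdp_per_capita * self.multiplier)


def wtp_threshold(gdp_per_capita: float, multiplier: float) -> Threshold:
    """Willingness-to-pay threshold = gdp_per_capita x multiplier."""
    return Threshold(gdp_per_capita=gdp_per_capita, multiplier=multiplier)


@dataclass(frozen=True)
class CEAResult:
    """Incremental verdict for intervention ``a`` against comparator ``b``."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    verdict: str
    nmb: dict[str, float]
    threshold: float

    def display_row(self) -> dict[str, object]:
        """Presentation rounding: cost to nearest dollar, effect to 3 dp."""
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "incremental_cost": round(self.delta_cost),
            "incremental_effect": round(self.delta_effect, 3),
            "icer": None if self.icer is None else round(self.icer, 2),
            "verdict": self.verdict,
        }


def compare_strategies(
    a: ArmResult, b: ArmResult, threshold: Threshold
) -> CEAResult:
    """Compare intervention ``a`` with comparator ``b``.

    Deltas are a minus b.  ``a`` is dominant when it is cheaper and more
    effective, dominated in the mirror case; otherwise the ICER
    delta_cost / delta_effect is compared with the threshold.  When the
    effect difference is exactly zero the verdict falls back to cost alone
    with no ICER; when both deltas are zero the verdict is indeterminate.
    """
    for r in (a, b):
        if not (math.isfinite(r.total_cost) and math.isfinite(r.total_qalys)):
            raise CEAError(f"non-finite arm result for {r.name!r}")
    dc = a.total_cost - b.total_cost
    de = a.total_qalys - b.total_qalys
    nmb = {
        a.name: a.total_qalys * threshold.value - a.total_cost,
        b.name: b.total_qalys * threshold.value - b.total_cost,
    }
    icer: float | None = None
    if de > 0 and dc < 0:
        verdict = "dominant"
    elif de < 0 and dc > 0:
        verdict = "dominated"
    elif de == 0:
        if dc == 0:
            verdict = "indeterminate"
        else:
            verdict = "dominant" if dc < 0 else "dominated"
    else:
        icer = dc / de
        verdict = (
            "icer_below_threshold" if icer <= threshold.value
            else "icer_above_threshold"
        )
    return CEAResult(
        intervention=a.name,
        comparator=b.name,
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        verdict=verdict,
        nmb=nmb,
        threshold=threshold.value,
    )
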