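"""Estimation of model inputs from patient-level records.

Three estimators feed the decision model:

* EQ-5D-3L utility summaries per (treatment arm, EDSS band) — sample mean and
  sample SD (n-1 denominator) of value-set scores;
* the pooled annual relapse rate per arm, total relapses divided by total
  person-years on drug;
* the societal cost breakdown per arm — item-level annual means within the
  direct medical (DMC), direct non-medical (DNMC) and indirect (IC)
  categories, with subtotals, grand total and percentage shares.

Monetary inputs collected in Iranian Rials are converted to purchasing-power
-parity dollars at the 2019 conversion factor of 22,075 Rials per PPP$.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from mscea.valuesets import ValueSet, validate_code

if TYPE_CHECKING:  # pragma: no cover
    from mscea.synthetic_cohort import PatientRecord

RIALS_PER_PPP_DOLLAR = 22_075.0

COST_CATEGORIES = ("DMC", "DNMC", "IC")


class EstimationError(ValueError):
    """Invalid input to an estimator (empty arm, unknown category, ...)."""


def score_eq5d(code: str, vs: ValueSet) -> float:
    """Utility of a single EQ-5D-3L response under a value set.

    Raises a domain error for codes outside ``^[123]{5}$``.
    """
    validate_code(code)
    return vs.score(code)


def ppp_convert(amount_rials: float) -> float:
    """Convert an amount in Iranian Rials to 2019 PPP dollars."""
    if amount_rials < 0:
        raise EstimationError(f"amount must be non-negative, got {amount_rials}")
    return amount_rials / RIALS_PER_PPP_DOLLAR


# --------------------------------------------------------------------- utility


@dataclass(frozen=True)
class UtilitySummary:
    """Per-(arm, EDSS band) utility moments.

    ``table`` has columns arm, edss_band, n, mean, sd, sd_degenerate; the
    sd_degenerate flag marks single-observation strata whose SD is reported
    as 0 by convention.
    """

    table: pd.DataFrame

    def stratum(self, arm: str, edss_band: str) -> pd.Series:
        sel = self.table[
            (self.table["arm"] == arm) & (self.table["edss_band"] == edss_band)
        ]
        if sel.empty:
            raise KeyError(f"no stratum ({arm}, {edss_band})")
        return sel.iloc[0]


def summarize_utilities(
    records: Iterable["PatientRecord"], vs: ValueSet
) -> UtilitySummary:
    """Sample mean and SD of value-set utilities per (arm, EDSS band).

    SD uses the n-1 denominator.  Strata present in the data with a single
    record get SD 0 and a degeneracy flag; strata absent from the data are
    simply omitted (with a warning when the cohort is non-empty but an arm
    has no records at all).
    """
    rows = [
        {
            "arm": r.arm,
            "edss_band": r.edss_band,
            "utility": score_eq5d(r.eq5d_code, vs),
        }
        for r in records
    ]
    if not rows:
        warnings.warn("no records: utility summary is empty", stacklevel=2)
        return UtilitySummary(
            pd.DataFrame(
                columns=["arm", "edss_band", "n", "mean", "sd", "sd_degenerate"]
            )
        )
    df = pd.DataFrame(rows)
    out = []
    for (arm, band), grp in df.groupby(["arm", "edss_band"], sort=True):
        n = len(grp)
        sd = float(grp["utility"].std(ddof=1)) if n > 1 else 0.0
        if n == 1:
            warnings.warn(
                f"stratum ({arm}, {band}) has a single record; SD reported as 0",
                stacklevel=2,
            )
        out.append(
            {
                "arm": arm,
                "edss_band": band,
                "n": n,
                "mean": float(grp["utility"].mean()),
                "sd": sd,
                "sd_degenerate": n == 1,
            }
        )
    return UtilitySummary(pd.DataFrame(out))


# --------------------------------------------------------------------- relapse


def mean_relapse_rate(
    records: Iterable["PatientRecord"], per_patient: bool = False
) -> dict[str, float]:
    """Pooled annual relapse rate per arm.

    The estimator is total relapses divided by total person-years on drug,
    per arm.  ``per_patient=True`` additionally divides the pooled rate by
    the number of patients in the arm, yielding a per-patient share of the
    annual rate rather than a rate; it is off by default because rates near
    one per year are the natural scale of the reported data.
    """
    by_arm: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        if r.years_on_drug <= 0:
            raise EstimationError(
                f"patient {r.patient_id}: years_on_drug must be positive"
            )
        by_arm.setdefault(r.arm, []).append((r.relapse_count, r.years_on_drug))
    if not by_arm:
        raise EstimationError("no records: cannot estimate relapse rate")
    out = {}
    for arm, pairs in by_arm.items():
        # fsum: correctly-rounded totals, invariant to patient ordering.
        rate = math.fsum(p[0] for p in pairs) / math.fsum(p[1] for p in pairs)
        if per_patient:
            rate /= len(pairs)
        out[arm] = rate
    return out


# ----------------------------------------------------------------------- costs


@dataclass(frozen=True)
class CostBreakdown:
    """Annual societal cost breakdown for one arm, in PPP$ per patient-year.

    ``items`` maps (category, item) -> mean annual amount; percentage shares
    are computed at two levels: each item's share of its category subtotal,
    and each category's share of the grand total.
    """

    items: dict[tuple[str, str], float]
    subtotals: dict[str, float] = field(init=False)
    grand_total: float = field(init=False)
    item_pct: dict[tuple[str, str], float] = field(init=False)
    category_pct: dict[str, float] = field(init=False)
    zero_total: bool = field(init=False)

    def __post_init__(self) -> None:
        for (cat, item), amount in self.items.items():
            if cat not in COST_CATEGORIES:
                raise EstimationError(
                    f"unknown cost category {cat!r} for item {item!r}; "
                    f"expected one of {COST_CATEGORIES}"
                )
            if amount < 0:
                raise EstimationError(f"negative cost for ({cat}, {item})")
        subtotals = {
            cat: sum(v for (c, _), v in self.items.items() if c == cat)
            for cat in COST_CATEGORIES
        }
        grand = sum(subtotals.values())
        zero = grand == 0.0
        if zero:
            warnings.warn(
                "all cost lines are zero; percentage shares reported as 0",
                stacklevel=2,
            )
        item_pct = {
            key: (100.0 * v / subtotals[key[0]] if subtotals[key[0]] > 0 else 0.0)
            for key, v in self.items.items()
        }
        cat_pct = {
            cat: (100.0 * sub / grand if grand > 0 else 0.0)
            for cat, sub in subtotals.items()
        }
        object.__setattr__(self, "subtotals", subtotals)
        object.__setattr__(self, "grand_total", grand)
        object.__setattr__(self, "item_pct", item_pct)
        object.__setattr__(self, "category_pct", cat_pct)
        object.__setattr__(self, "zero_total", zero)

    @classmethod
    def from_item_means(
        cls, item_means: dict[str, dict[str, float]]
    ) -> "CostBreakdown":
        """Build a breakdown directly from per-item annual means.

        ``item_means`` is nested as category -> item -> mean amount, the
        layout of a published mean-annual-cost table.
        """
        flat = {
            (cat, item): float(v)
            for cat, items in item_means.items()
            for item, v in items.items()
        }
        return cls(items=flat)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring a published cost table."""
        rows = []
        for cat in COST_CATEGORIES:
            for (c, item), v in sorted(self.items.items()):
                if c != cat:
                    continue
                rows.append(
                    {
                        "category": cat,
                        "item": item,
                        "mean_ppp": v,
                        "pct_of_category": self.item_pct[(c, item)],
                    }
                )
            rows.append(
                {
                    "category": cat,
                    "item": "Total",
                    "mean_ppp": self.subtotals[cat],
                    "pct_of_category": self.category_pct[cat],
                }
            )
        rows.append(
            {
                "category": "ALL",
                "item": "Total Costs",
                "mean_ppp": self.grand_total,
                "pct_of_category": 0.0 if self.zero_total else 100.0,
            }
        )
        return pd.DataFrame(rows)


def aggregate_costs(
    records: Sequence["PatientRecord"],
) -> dict[str, CostBreakdown]:
    """Per-arm annual cost breakdown from patient-level cost lines.

    Each cost line carries an annual amount; the item mean is the arithmetic
    mean over all patients in the arm, counting patients without the item
    as zero.  Additive by construction: pooling two sub-cohorts of an arm
    reproduces the pooled breakdown exactly.
    """
    by_arm: dict[str, list["PatientRecord"]] = {}
    for r in records:
        by_arm.setdefault(r.arm, []).append(r)
    if not by_arm:
        raise EstimationError("no records: cannot aggregate costs")
    out: dict[str, CostBreakdown] = {}
    for arm, arm_records in sorted(by_arm.items()):
        n = len(arm_records)
        sums: dict[tuple[str, str], float] = {}
        for r in arm_records:
            for line in r.cost_lines:
                if line.category not in COST_CATEGORIES:
                    raise EstimationError(
                        f"patient {r.patient_id}: unknown cost category "
                        f"{line.category!r}"
                    )
                key = (line.category, line.item)
                sums[key] = sums.get(key, 0.0) + line.amount
        out[arm] = CostBreakdown(items={k: v / n for k, v in sums.items()})
    return out
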