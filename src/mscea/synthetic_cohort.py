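"""Synthetic patient-level cohort with the statistical structure of the study.

The generator emulates a two-arm observational sample: n per arm, a fixed
female fraction, arm-specific age distributions truncated to a plausible
adult range, an enrollment EDSS band, an EQ-5D-3L response code, a relapse
history, and annual cost line items.

Utility targets are realized indirectly: a latent utility is drawn from a
beta distribution moment-matched to the target mean/SD on the value set's
score range, then snapped to the EQ-5D-3L code whose score is nearest, so
the downstream scoring path is exercised end to end.  Relapse counts are
Poisson with mean = target annual rate x years on drug; years on drug are
1 + Exponential(mean 2 years), truncated at 10, respecting the study's
minimum-one-year inclusion criterion.  Cost lines are annual use count x
unit price with small multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from mscea.empirical_inputs import COST_CATEGORIES
from mscea.valuesets import ValueSet, ValueSetError, synthetic_reference, validate_code

EDSS_BANDS = ("edss_0_2_5", "edss_3_5_5")

# Years-on-drug distribution: inclusion floor + exponential excess, capped.
YEARS_MIN = 1.0
YEARS_EXCESS_MEAN = 2.0
YEARS_MAX = 10.0
COST_NOISE_SIGMA = 0.10  # log-normal sigma of the multiplicative cost noise


class ValidationError(ValueError):
    """A cohort spec or record field violates its invariants."""


class CohortParseError(ValueError):
    """A cohort file row could not be parsed; message carries the line number."""


class CostLine(NamedTuple):
    category: str  # DMC | DNMC | IC
    item: str
    amount: float  # annual PPP$


@dataclass(frozen=True)
class PatientRecord:
    """One study participant."""

    patient_id: str
    arm: str
    age: float
    sex: str  # "F" | "M"
    edss_band: str
    eq5d_code: str
    relapse_count: int
    years_on_drug: float
    cost_lines: tuple[CostLine, ...]

    def __post_init__(self) -> None:
        try:
            validate_code(self.eq5d_code)
        except ValueSetError as exc:
            raise ValidationError(str(exc)) from None
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.patient_id}: sex must be F or M")
        if self.edss_band not in EDSS_BANDS:
            raise ValidationError(
                f"{self.patient_id}: edss_band must be one of {EDSS_BANDS}"
            )
        if self.years_on_drug < YEARS_MIN:
            raise ValidationError(
                f"{self.patient_id}: years_on_drug must be >= {YEARS_MIN} "
                "(study inclusion criterion)"
            )
        if self.relapse_count < 0:
            raise ValidationError(f"{self.patient_id}: negative relapse_count")
        for line in self.cost_lines:
            if line.category not in COST_CATEGORIES:
                raise ValidationError(
                    f"{self.patient_id}: unknown cost category {line.category!r}"
                )
            if line.amount < 0:
                raise ValidationError(
                    f"{self.patient_id}: negative cost amount for {line.item!r}"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Targets the generated sample must recover in expectation."""

    n_per_arm: int = 60
    female_fraction: float = 0.7417
    age_mean_by_arm: dict[str, float] = field(
        default_factory=lambda: {"natalizumab": 33.4, "rituximab": 34.92}
    )
    age_sd_by_arm: dict[str, float] = field(
        default_factory=lambda: {"natalizumab": 7.27, "rituximab": 5.94}
    )
    age_bounds: tuple[float, float] = (18.0, 65.0)
    edss_band_probs: dict[str, float] = field(
        default_factory=lambda: {"edss_0_2_5": 1.0, "edss_3_5_5": 0.0}
    )
    # arm -> band -> (mean, sd)
    utility_targets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    relapse_targets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    # arm -> list of (category, item, annual count, unit price)
    cost_menu: dict[str, list[tuple[str, str, float, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise ValidationError(f"n_per_arm must be >= 0, got {self.n_per_arm}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValidationError(
                f"female_fraction must be in [0, 1], got {self.female_fraction}"
            )
        for arm, sd in self.age_sd_by_arm.items():
            if sd <= 0:
                raise ValidationError(f"age_sd_by_arm[{arm!r}] must be > 0")
        total = sum(self.edss_band_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"edss_band_probs must sum to 1, got {total!r}"
            )
        for arm, targets in self.utility_targets.items():
            for band, (_, sd) in targets.items():
                if sd < 0:
                    raise ValidationError(
                        f"utility_targets[{arm!r}][{band!r}]: SD must be >= 0"
                    )
        for arm, menu in self.cost_menu.items():
            for cat, item, count, price in menu:
                if count < 0 or price < 0:
                    raise ValidationError(
                        f"cost_menu[{arm!r}] item {item!r}: "
                        "count and unit price must be >= 0"
                    )
                if cat not in COST_CATEGORIES:
                    raise ValidationError(
                        f"cost_menu[{arm!r}] item {item!r}: "
                        f"unknown category {cat!r}"
                    )

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(sorted(self.age_mean_by_arm))

    @classmethod
    def from_config(cls, cfg: dict, seed: int = 0) -> "CohortSpec":
        """Build from the ``cohort`` block of a model configuration."""
        c = cfg["cohort"]
        return cls(
            n_per_arm=int(c["n_per_arm"]),
            female_fraction=float(c["female_fraction"]),
            age_mean_by_arm={a: float(v) for a, v in c["age_mean"].items()},
            age_sd_by_arm={a: float(v) for a, v in c["age_sd"].items()},
            age_bounds=tuple(c.get("age_bounds", (18.0, 65.0))),
            edss_band_probs={b: float(p) for b, p in c["edss_band_probs"].items()},
            utility_targets={
                a: {b: (float(m), float(s)) for b, (m, s) in t.items()}
                for a, t in c["utility_targets"].items()
            },
            relapse_targets={
                a: {b: (float(m), float(s)) for b, (m, s) in t.items()}
                for a, t in c["relapse_targets"].items()
            },
            cost_menu={
                a: [
                    (
                        str(e["category"]),
                        str(e["item"]),
                        float(e["count"]),
                        float(e["unit_price"]),
                    )
                    for e in menu
                ]
                for a, menu in c["cost_menu"].items()
            },
            seed=seed,
        )


# ---------------------------------------------------------------- generation


def _code_grid(vs: ValueSet) -> tuple[np.ndarray, list[str]]:
    """Scores and codes sorted by (score, code): the snapping grid."""
    pairs = sorted(vs.scores.items(), key=lambda kv: (kv[1], kv[0]))
    codes = [c for c, _ in pairs]
    scores = np.array([s for _, s in pairs])
    return scores, codes


def _nearest_codes(targets: np.ndarray, scores: np.ndarray, codes: list[str]) -> list[str]:
    idx = np.searchsorted(scores, targets)
    idx = np.clip(idx, 1, len(scores) - 1)
    left = scores[idx - 1]
    right = scores[idx]
    # Ties go to the lower score, whose first occurrence in the (score, code)
    # sort is the lexicographically smallest code with that score.
    pick = np.where(targets - left <= right - targets, idx - 1, idx)
    return [codes[i] for i in pick]


def _draw_latent_utilities(
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Moment-matched beta on [lo, hi]; truncated normal if beta infeasible."""
    if sd < 1e-9:
        return np.full(size, mean)
    span = hi - lo
    m = (mean - lo) / span
    v = (sd / span) ** 2
    if 0.0 < m < 1.0 and v < m * (1.0 - m):
        nu = m * (1.0 - m) / v - 1.0
        draws = rng.beta(m * nu, (1.0 - m) * nu, size=size)
        return lo + span * draws
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec, value_set: ValueSet | None = None
) -> list[PatientRecord]:
    """Draw a full two-arm cohort; deterministic given ``spec.seed``."""
    vs = value_set if value_set is not None else synthetic_reference()
    scores, codes = _code_grid(vs)
    lo, hi = float(scores[0]), float(scores[-1])
    rng = np.random.default_rng(spec.seed)
    bands = list(spec.edss_band_probs)
    band_p = np.array([spec.edss_band_probs[b] for b in bands])

    records: list[PatientRecord] = []
    for arm in spec.arms:
        n = spec.n_per_arm
        if n == 0:
            continue
        mu = spec.age_mean_by_arm[arm]
        sd = spec.age_sd_by_arm[arm]
        a, b = (spec.age_bounds[0] - mu) / sd, (spec.age_bounds[1] - mu) / sd
        ages = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        sexes = np.where(rng.random(n) < spec.female_fraction, "F", "M")
        band_idx = rng.choice(len(bands), size=n, p=band_p)
        years = YEARS_MIN + rng.exponential(YEARS_EXCESS_MEAN, size=n)
        years = np.minimum(years, YEARS_MAX)

        # Latent utilities per band, snapped to the nearest code score.
        latent = np.empty(n)
        for bi, band in enumerate(bands):
            mask = band_idx == bi
            if not mask.any():
                continue
            mean_u, sd_u = spec.utility_targets.get(arm, {}).get(band, (0.7, 0.15))
            latent[mask] = _draw_latent_utilities(
                mean_u, sd_u, lo, hi, int(mask.sum()), rng
            )
        eq5d = _nearest_codes(latent, scores, codes)

        rates = np.array(
            [
                spec.relapse_targets.get(arm, {}).get(bands[bi], (0.5, 0.5))[0]
                for bi in band_idx
            ]
        )
        relapses = rng.poisson(rates * years)

        menu = spec.cost_menu.get(arm, [])
        noise = (
            rng.lognormal(
                -0.5 * COST_NOISE_SIGMA**2, COST_NOISE_SIGMA, size=(n, len(menu))
            )
            if menu
            else np.zeros((n, 0))
        )
        for i in range(n):
            lines = tuple(
                CostLine(cat, item, float(count * price * noise[i, j]))
                for j, (cat, item, count, price) in enumerate(menu)
            )
            records.append(
                PatientRecord(
                    patient_id=f"{arm[:3]}-{i:04d}",
                    arm=arm,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    edss_band=bands[band_idx[i]],
                    eq5d_code=eq5d[i],
                    relapse_count=int(relapses[i]),
                    years_on_drug=float(years[i]),
                    cost_lines=lines,
                )
            )
    return records


# ------------------------------------------------------------------------- io

_PATIENT_COLUMNS = (
    "patient_id",
    "arm",
    "age",
    "sex",
    "edss_band",
    "eq5d_code",
    "relapse_count",
    "years_on_drug",
)
_COST_COLUMNS = ("patient_id", "category", "item", "amount")
PATIENT_FILE = "cohort.tsv"
COST_FILE = "cohort_costs.tsv"


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort to ``path`` (a directory): a patient table plus a
    long-format companion file of cost lines keyed by patient_id.

    Floats are written with full ``repr`` precision so that
    ``read_cohort(write_cohort(x)) == x`` field for field.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / PATIENT_FILE, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PATIENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.patient_id}\t{r.arm}\t{r.age!r}\t{r.sex}\t{r.edss_band}\t"
                f"{r.eq5d_code}\t{r.relapse_count}\t{r.years_on_drug!r}\n"
            )
    with open(path / COST_FILE, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COST_COLUMNS) + "\n")
        for r in records:
            for line in r.cost_lines:
                fh.write(
                    f"{r.patient_id}\t{line.category}\t{line.item}\t{line.amount!r}\n"
                )


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort written by :func:`write_cohort`.

    Malformed rows raise :class:`CohortParseError` naming the file and line;
    invalid field values (e.g. an out-of-range EQ-5D digit) surface the
    underlying validation message.
    """
    path = Path(path)
    cost_lines: dict[str, list[CostLine]] = {}
    cost_file = path / COST_FILE
    if cost_file.exists():
        with open(cost_file, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != _COST_COLUMNS:
                raise CohortParseError(
                    f"{cost_file}:1: unexpected header {header}"
                )
            for lineno, raw in enumerate(fh, start=2):
                parts = raw.rstrip("\n").split("\t")
                if len(parts) != len(_COST_COLUMNS):
                    raise CohortParseError(
                        f"{cost_file}:{lineno}: expected "
                        f"{len(_COST_COLUMNS)} columns, got {len(parts)}"
                    )
                pid, cat, item, amount = parts
                try:
                    value = float(amount)
                except ValueError:
                    raise CohortParseError(
                        f"{cost_file}:{lineno}: non-numeric amount {amount!r}"
                    ) from None
                cost_lines.setdefault(pid, []).append(CostLine(cat, item, value))

    records: list[PatientRecord] = []
    patient_file = path / PATIENT_FILE
    with open(patient_file, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _PATIENT_COLUMNS:
            raise CohortParseError(f"{patient_file}:1: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(_PATIENT_COLUMNS):
                raise CohortParseError(
                    f"{patient_file}:{lineno}: expected "
                    f"{len(_PATIENT_COLUMNS)} columns, got {len(parts)}"
                )
            pid, arm, age, sex, band, code, relapses, years = parts
            try:
                record = PatientRecord(
                    patient_id=pid,
                    arm=arm,
                    age=float(age),
                    sex=sex,
                    edss_band=band,
                    eq5d_code=code,
                    relapse_count=int(relapses),
                    years_on_drug=float(years),
                    cost_lines=tuple(cost_lines.get(pid, ())),
                )
            except (ValueError, ValidationError) as exc:
                raise CohortParseError(f"{patient_file}:{lineno}: {exc}") from None
            records.append(record)
    return records


def expected_micro_costs(spec: CohortSpec, arm: str) -> dict[tuple[str, str], float]:
    """Expected annual amount per menu item (count x unit price).

    The multiplicative noise has mean one, so these are the generator's
    exact expected cost-line values.
    """
    return {
        (cat, item): count * price
        for cat, item, count, price in spec.cost_menu.get(arm, [])
    }
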