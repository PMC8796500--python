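"""Annual-cycle lifetime Markov cohort model over EDSS bands with death.

The cohort starts at a given age distributed over the four living EDSS bands
and is propagated one year at a time through a 5x5 row-stochastic transition
matrix (four living states plus absorbing death).  Each cycle accrues costs,
quality-adjusted life-years and expected relapses from the occupancy at the
start of the cycle; accruals are discounted at separate annual rates for
costs and outcomes.

Published transition evidence arrives as conditional percentages among
survivors (rows summing to ~100) alongside a separate per-state annual death
probability, so the full matrix is composed by applying death first and
distributing survivors proportionally to the re-normalized living row.
Clinical-trial rates are converted to per-cycle probabilities with
``p = 1 - exp(-r t)``.

Relapses accrue only in the relapsing-remitting states (EDSS 0-5.5), at the
drug-specific annual probability, while disease-modifying therapy is active;
therapy stops on entry to the secondary-progressive states, where the drug
cost component also stops.  Relapses are a counted outcome only — they feed
no disutility or cost back into the QALY/cost streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from mscea.states import (
    DEATH,
    LIVING_STATES,
    N_LIVING,
    RRMS_STATES,
    STATE_INDEX,
)

ROW_SUM_TOLERANCE = 0.05  # percentage points of rounding slack per living row


class ModelError(ValueError):
    """Invalid model structure or parameters."""


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Convert an event rate to a probability over time ``t``: 1 - exp(-rt)."""
    if rate < 0:
        raise ModelError(f"rate must be non-negative, got {rate}")
    if t <= 0:
        raise ModelError(f"time must be positive, got {t}")
    return -np.expm1(-rate * t)


def discount(value: float, rate: float, cycle_index: int) -> float:
    """Present value of ``value`` accrued at ``cycle_index`` (annual rate)."""
    if rate < 0:
        raise ModelError(f"discount rate must be non-negative, got {rate}")
    return value / (1.0 + rate) ** cycle_index


@dataclass(frozen=True)
class TransitionTable:
    """Annual transition evidence: living-row percentages and death column.

    ``living_rows[i, j]`` is the percentage transitioning from living state i
    to living state j conditional on survival; ``death_probs[i]`` is the
    annual probability of death (percent) from state i.
    """

    living_rows: np.ndarray  # (4, 4) percent
    death_probs: np.ndarray  # (4,) percent

    def __post_init__(self) -> None:
        living = np.asarray(self.living_rows, dtype=float)
        death = np.asarray(self.death_probs, dtype=float)
        object.__setattr__(self, "living_rows", living)
        object.__setattr__(self, "death_probs", death)
        if living.shape != (N_LIVING, N_LIVING):
            raise ModelError(
                f"living_rows must be {N_LIVING}x{N_LIVING}, got {living.shape}"
            )
        if death.shape != (N_LIVING,):
            raise ModelError(f"death_probs must have length {N_LIVING}")
        if (living < 0).any():
            raise ModelError("living_rows entries must be non-negative")
        if ((death < 0) | (death > 100)).any():
            raise ModelError("death_probs must lie in [0, 100] percent")
        sums = living.sum(axis=1)
        bad = np.abs(sums - 100.0) > ROW_SUM_TOLERANCE
        if bad.any():
            i = int(np.argmax(bad))
            raise ModelError(
                f"living row {LIVING_STATES[i]!r} sums to {sums[i]:.4f}%, "
                f"outside 100 +/- {ROW_SUM_TOLERANCE}"
            )

    @classmethod
    def from_dicts(
        cls,
        living_rows: dict[str, Iterable[float]],
        death_probs: dict[str, float],
    ) -> "TransitionTable":
        rows = np.array([list(living_rows[s]) for s in LIVING_STATES], float)
        death = np.array([death_probs[s] for s in LIVING_STATES], float)
        return cls(living_rows=rows, death_probs=death)


def build_transition_matrix(tt: TransitionTable) -> np.ndarray:
    """Full 5x5 row-stochastic matrix (living states in order, then death).

    Row for living state s: P(s -> death) = d_s; P(s -> j) = (1 - d_s) times
    the re-normalized living-row share.  The death row is the identity.
    Rows sum to 1 within 1e-12.
    """
    d = tt.death_probs / 100.0
    living = tt.living_rows / tt.living_rows.sum(axis=1, keepdims=True)
    m = np.zeros((N_LIVING + 1, N_LIVING + 1))
    m[:N_LIVING, :N_LIVING] = (1.0 - d)[:, None] * living
    m[:N_LIVING, N_LIVING] = d
    m[N_LIVING, N_LIVING] = 1.0
    err = np.abs(m.sum(axis=1) - 1.0).max()
    if err > 1e-12:
        raise ModelError(f"composed matrix rows deviate from 1 by {err:.2e}")
    return m


@dataclass(frozen=True)
class ArmParameters:
    """One strategy's inputs: relapse risk, utilities and annual costs.

    ``state_costs`` are decomposed into an annual drug-acquisition cost,
    charged only while the patient occupies a DMT-active state, and an
    annual non-drug cost per state.  Utilities apply per living state.
    """

    name: str
    annual_relapse_prob: float
    state_utilities: dict[str, float]
    drug_cost: float
    other_costs: dict[str, float]
    dmt_active_states: tuple[str, ...] = RRMS_STATES

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_relapse_prob <= 1.0:
            raise ModelError(
                f"{self.name}: annual_relapse_prob must be in [0, 1], "
                f"got {self.annual_relapse_prob}"
            )
        for s in LIVING_STATES:
            if s not in self.state_utilities:
                raise ModelError(f"{self.name}: missing utility for state {s!r}")
            if self.state_utilities[s] > 1.0:
                raise ModelError(
                    f"{self.name}: utility for {s!r} exceeds 1.0"
                )
            if s not in self.other_costs:
                raise ModelError(f"{self.name}: missing other_costs for state {s!r}")
            if self.other_costs[s] < 0:
                raise ModelError(f"{self.name}: negative cost for {s!r}")
        if self.drug_cost < 0:
            raise ModelError(f"{self.name}: negative drug_cost")
        unknown = set(self.dmt_active_states) - set(LIVING_STATES)
        if unknown:
            raise ModelError(f"{self.name}: unknown dmt_active_states {unknown}")

    def utility_vector(self) -> np.ndarray:
        return np.array([self.state_utilities[s] for s in LIVING_STATES])

    def cost_vector(self) -> np.ndarray:
        active = np.array([s in self.dmt_active_states for s in LIVING_STATES])
        other = np.array([self.other_costs[s] for s in LIVING_STATES])
        return other + self.drug_cost * active

    def relapse_vector(self) -> np.ndarray:
        rrms = np.array([s in RRMS_STATES for s in LIVING_STATES])
        active = np.array([s in self.dmt_active_states for s in LIVING_STATES])
        return self.annual_relapse_prob * (rrms & active)


@dataclass(frozen=True)
class ModelSettings:
    """Run-level conventions: horizon, discounting, cycle timing."""

    start_age: float = 34.0
    max_age: float = 100.0
    cycle_length: float = 1.0
    start_distribution: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    discount_rate_costs: float = 0.058
    discount_rate_outcomes: float = 0.03
    survival_floor: float = 1e-6
    half_cycle_correction: bool = False
    discount_first_cycle: bool = False

    def __post_init__(self) -> None:
        if self.discount_rate_costs < 0 or self.discount_rate_outcomes < 0:
            raise ModelError("discount rates must be non-negative")
        start = np.asarray(self.start_distribution, float)
        if start.shape != (N_LIVING,) or (start < 0).any():
            raise ModelError(
                f"start_distribution must be {N_LIVING} non-negative shares"
            )
        if abs(start.sum() - 1.0) > 1e-9:
            raise ModelError(
                f"start_distribution sums to {start.sum()!r}, expected 1"
            )
        if self.max_age <= self.start_age:
            raise ModelError("max_age must exceed start_age")

    @property
    def n_cycles(self) -> int:
        return int(round((self.max_age - self.start_age) / self.cycle_length))


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancies and accruals of one model run."""

    cycles: np.ndarray        # cycle index k = 0, 1, ...
    ages: np.ndarray
    occupancy: np.ndarray     # (n_cycles, 4) at the start of each cycle
    cum_death: np.ndarray
    cost: np.ndarray          # undiscounted per-cycle accrual
    qaly: np.ndarray
    relapses: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    disc_relapses: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": self.cycles,
                "age": self.ages,
                **{
                    f"occ_{s}": self.occupancy[:, i]
                    for i, s in enumerate(LIVING_STATES)
                },
                "cum_death": self.cum_death,
                "cost": self.cost,
                "qaly": self.qaly,
                "relapses": self.relapses,
                "disc_cost": self.disc_cost,
                "disc_qaly": self.disc_qaly,
                "disc_relapses": self.disc_relapses,
            }
        )
        return df


@dataclass(frozen=True)
class ArmResult:
    """Lifetime totals for one strategy (discounted unless noted)."""

    name: str
    total_cost: float
    total_qalys: float
    total_relapses: float
    life_years: float  # undiscounted


def run_cohort(
    tt: TransitionTable,
    arm: ArmParameters,
    settings: ModelSettings,
    keep_trace: bool = True,
) -> tuple[CohortTrace | None, ArmResult]:
    """Propagate the cohort over the lifetime horizon and accrue outcomes.

    Accruals for cycle k use the occupancy at the start of the cycle
    (so a cohort annihilated by the first transition still accrues its first
    cycle) and are discounted by (1 + r)^(-k); with
    ``settings.discount_first_cycle`` the exponent starts at 1.  Optional
    half-cycle correction averages start- and end-of-cycle occupancy.
    The run stops at ``max_age`` or when survival falls below
    ``survival_floor``, whichever comes first.
    """
    matrix = build_transition_matrix(tt)
    if np.abs(matrix.sum(axis=1) - 1.0).max() > 1e-12 or (matrix < 0).any():
        raise ModelError("transition matrix is not row-stochastic")
    m_living = matrix[:N_LIVING, :N_LIVING]
    m_death = matrix[:N_LIVING, N_LIVING]

    u = arm.utility_vector()
    c = arm.cost_vector()
    rel = arm.relapse_vector()

    occ = np.asarray(settings.start_distribution, float).copy()
    cum_death = 0.0
    offset = 1 if settings.discount_first_cycle else 0
    vc = 1.0 + settings.discount_rate_costs
    vo = 1.0 + settings.discount_rate_outcomes

    rows: list[tuple] = []
    tot_dc = tot_dq = tot_dr = tot_ly = 0.0
    for k in range(settings.n_cycles):
        alive = occ.sum()
        if alive < settings.survival_floor:
            break
        occ_next = occ @ m_living
        deaths_k = float(occ @ m_death)
        basis = 0.5 * (occ + occ_next) if settings.half_cycle_correction else occ

        cost_k = float(basis @ c)
        qaly_k = float(basis @ u)
        rel_k = float(basis @ rel)
        dfc = vc ** -(k + offset)
        dfo = vo ** -(k + offset)

        tot_dc += cost_k * dfc
        tot_dq += qaly_k * dfo
        tot_dr += rel_k * dfo
        tot_ly += float(basis.sum())
        if keep_trace:
            rows.append(
                (
                    k,
                    settings.start_age + k * settings.cycle_length,
                    occ.copy(),
                    cum_death,
                    cost_k,
                    qaly_k,
                    rel_k,
                    cost_k * dfc,
                    qaly_k * dfo,
                    rel_k * dfo,
                )
            )
        occ = occ_next
        cum_death += deaths_k

    result = ArmResult(
        name=arm.name,
        total_cost=tot_dc,
        total_qalys=tot_dq,
        total_relapses=tot_dr,
        life_years=tot_ly,
    )
    if not keep_trace:
        return None, result
    trace = CohortTrace(
        cycles=np.array([r[0] for r in rows]),
        ages=np.array([r[1] for r in rows]),
        occupancy=np.array([r[2] for r in rows]),
        cum_death=np.array([r[3] for r in rows]),
        cost=np.array([r[4] for r in rows]),
        qaly=np.array([r[5] for r in rows]),
        relapses=np.array([r[6] for r in rows]),
        disc_cost=np.array([r[7] for r in rows]),
        disc_qaly=np.array([r[8] for r in rows]),
        disc_relapses=np.array([r[9] for r in rows]),
    )
    return trace, result


def simulate_individuals(
    tt: TransitionTable,
    arm: ArmParameters,
    settings: ModelSettings,
    n_patients: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """First-order microsimulation of individual disease trajectories.

    Draws ``n_patients`` independent state paths from the same transition
    matrix as the cohort model and accrues the same per-cycle outcomes.
    Returns the mean discounted QALY and cost per patient with Monte-Carlo
    standard errors; serves as an independent stochastic cross-check of the
    cohort expectation.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    matrix = build_transition_matrix(tt)
    cum = matrix.cumsum(axis=1)
    u = np.append(arm.utility_vector(), 0.0)
    c = np.append(arm.cost_vector(), 0.0)
    start = np.asarray(settings.start_distribution, float)
    death_idx = N_LIVING

    states = rng.choice(N_LIVING, size=n_patients, p=start)
    qalys = np.zeros(n_patients)
    costs = np.zeros(n_patients)
    offset = 1 if settings.discount_first_cycle else 0
    vo = 1.0 + settings.discount_rate_outcomes
    vc = 1.0 + settings.discount_rate_costs
    for k in range(settings.n_cycles):
        alive = states != death_idx
        if not alive.any():
            break
        qalys += u[states] * vo ** -(k + offset)
        costs += c[states] * vc ** -(k + offset)
        draws = rng.random(alive.sum())
        nxt = np.empty(int(alive.sum()), dtype=int)
        alive_states = states[alive]
        for s in range(N_LIVING):
            mask = alive_states == s
            if mask.any():
                nxt[mask] = np.searchsorted(cum[s], draws[mask], side="right")
        states[alive] = nxt
    n = float(n_patients)
    return {
        "mean_qaly": float(qalys.mean()),
        "se_qaly": float(qalys.std(ddof=1) / np.sqrt(n)),
        "mean_cost": float(costs.mean()),
        "se_cost": float(costs.std(ddof=1) / np.sqrt(n)),
    }
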