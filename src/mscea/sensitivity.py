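"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis perturbs each cost and utility parameter by a
fixed fraction (default +/-20%) and reruns the full model, producing a
tornado table.  The probabilistic analysis is a second-order Monte-Carlo
simulation: utilities are drawn from beta distributions and costs from gamma
distributions, both parameterized by method of moments from the reported
mean and SD, every distributed parameter is redrawn independently each
iteration, and the lifetime model is rerun per arm per draw.  Draws are
summarized as a cost-effectiveness acceptability curve (probability of the
highest net monetary benefit across a willingness-to-pay grid, ties split
equally) and as quadrant proportions on the incremental cost-effectiveness
plane.

Transition probabilities are not sampled: parameter uncertainty is confined
to the utility and cost inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mscea.config import (
    arm_names,
    build_arm,
    build_settings,
    build_threshold,
    build_transition_table,
    get_path,
    set_path,
    threshold_grid,
)
from mscea.markov_engine import ArmResult, run_cohort
from mscea.states import LIVING_STATES


class SensitivityError(ValueError):
    pass


class InfeasibleDistributionError(SensitivityError):
    """Requested moments admit no distribution in the chosen family."""


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters (alpha, beta).

    Requires ``mean`` in (0, 1) and ``sd**2 < mean * (1 - mean)``; the fitted
    distribution reproduces the input moments exactly.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleDistributionError(
            f"beta mean must be in (0, 1), got {mean}"
        )
    if sd <= 0:
        raise InfeasibleDistributionError(f"beta sd must be positive, got {sd}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleDistributionError(
            f"beta infeasible: sd^2 = {var:.6g} >= mean(1-mean) = "
            f"{mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale); moments recovered exactly."""
    if mean <= 0 or sd <= 0:
        raise InfeasibleDistributionError(
            f"gamma requires positive mean and sd, got mean={mean}, sd={sd}"
        )
    var = sd * sd
    return mean * mean / var, var / mean


@dataclass(frozen=True)
class DistributionSpec:
    """One distributed parameter: dotted config path, family and moments."""

    path: str
    family: str  # "beta" | "gamma"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma"):
            raise SensitivityError(f"unknown family {self.family!r}")
        # Fitting validates feasibility eagerly.
        self.fit()

    def fit(self) -> tuple[float, float]:
        if self.family == "beta":
            return beta_from_moments(self.mean, self.sd)
        return gamma_from_moments(self.mean, self.sd)

    def draw(self, rng: np.random.Generator) -> float:
        a, b = self.fit()
        if self.family == "beta":
            return float(rng.beta(a, b))
        return float(rng.gamma(a, b))


@dataclass(frozen=True)
class PSAConfig:
    """Monte-Carlo settings: iteration count, master seed, specs, CEAC grid."""

    specs: tuple[DistributionSpec, ...]
    n_iterations: int = 5000
    seed: int = 0
    thresholds: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise SensitivityError("n_iterations must be >= 1")
        th = tuple(float(t) for t in self.thresholds)
        if any(t < 0 for t in th):
            raise SensitivityError("thresholds must be non-negative")
        if list(th) != sorted(th):
            raise SensitivityError("thresholds must be sorted ascending")
        object.__setattr__(self, "thresholds", th)
        object.__setattr__(self, "specs", tuple(self.specs))


def default_psa_specs(cfg: dict, cost_cv: float | None = None) -> list[DistributionSpec]:
    """Beta specs for every (arm, state) utility and gamma specs for every
    cost parameter, with SDs from the config (utilities) or a coefficient of
    variation (costs, default from ``psa.cost_cv``)."""
    if cost_cv is None:
        cost_cv = float(cfg.get("psa", {}).get("cost_cv", 0.2))
    specs: list[DistributionSpec] = []
    for arm, spec in cfg["arms"].items():
        sds = spec.get("utility_sds", {})
        for s in LIVING_STATES:
            mean = float(spec["utilities"][s])
            sd = float(sds.get(s, 0.1))
            specs.append(
                DistributionSpec(f"arms.{arm}.utilities.{s}", "beta", mean, sd)
            )
        drug = float(spec["drug_cost"])
        if drug > 0:
            specs.append(
                DistributionSpec(
                    f"arms.{arm}.drug_cost", "gamma", drug, cost_cv * drug
                )
            )
        for s in LIVING_STATES:
            c = float(spec["other_costs"][s])
            if c > 0:
                specs.append(
                    DistributionSpec(
                        f"arms.{arm}.other_costs.{s}", "gamma", c, cost_cv * c
                    )
                )
    return specs


def evaluate_config(cfg: dict, keep_trace: bool = False):
    """Run the lifetime model for both arms of a config.

    Returns ``(results, traces)`` keyed by arm name; traces are ``None``
    unless requested.
    """
    tt = build_transition_table(cfg)
    settings = build_settings(cfg)
    results: dict[str, ArmResult] = {}
    traces: dict[str, object] = {}
    for name in cfg["arms"]:
        trace, res = run_cohort(tt, build_arm(cfg, name), settings, keep_trace)
        results[name] = res
        traces[name] = trace
    return results, traces


# ------------------------------------------------------------------------ PSA


def _model_subset(cfg: dict) -> dict:
    import copy

    return copy.deepcopy(
        {k: cfg[k] for k in ("transition_table", "settings", "threshold", "arms")}
    )


def run_psa(cfg: dict, psa_cfg: PSAConfig) -> pd.DataFrame:
    """Second-order Monte-Carlo propagation of parameter uncertainty.

    Each iteration draws every distributed parameter independently from its
    fitted distribution, reruns the lifetime model per arm, and records the
    drawn values and outcomes.  A master seed spawns one substream per
    iteration, so results do not depend on execution order.

    Returns a DataFrame with one row per iteration: ``cost_<arm>``,
    ``qaly_<arm>``, ``delta_cost``, ``delta_qaly`` (intervention minus
    comparator) and one ``param:<path>`` column per spec.
    """
    a_name, b_name = arm_names(cfg)
    base = _model_subset(cfg)
    tt = build_transition_table(base)
    settings = build_settings(base)
    children = np.random.SeedSequence(psa_cfg.seed).spawn(psa_cfg.n_iterations)
    rows = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        draws = {spec.path: spec.draw(rng) for spec in psa_cfg.specs}
        for path, value in draws.items():
            set_path(base, path, value)
        row: dict[str, float] = {"iteration": i}
        for name in (a_name, b_name):
            _, res = run_cohort(tt, build_arm(base, name), settings, False)
            row[f"cost_{name}"] = res.total_cost
            row[f"qaly_{name}"] = res.total_qalys
        row["delta_cost"] = row[f"cost_{a_name}"] - row[f"cost_{b_name}"]
        row["delta_qaly"] = row[f"qaly_{a_name}"] - row[f"qaly_{b_name}"]
        for path, value in draws.items():
            row[f"param:{path}"] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["intervention"] = a_name
    df.attrs["comparator"] = b_name
    return df


def ceac(
    samples: pd.DataFrame, thresholds: np.ndarray | tuple[float, ...]
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    For each threshold, the fraction of iterations in which each strategy
    attains the higher net monetary benefit; exact ties are split equally,
    so the two fractions sum to 1.
    """
    thresholds = np.asarray(list(thresholds), float)
    if thresholds.size == 0:
        raise SensitivityError("thresholds grid is empty")
    if len(samples) == 0:
        raise SensitivityError("no PSA samples")
    a = samples.attrs.get("intervention", "intervention")
    b = samples.attrs.get("comparator", "comparator")
    de = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    rows = []
    for lam in thresholds:
        dnmb = lam * de - dc
        p_a = float(np.mean(np.where(dnmb > 0, 1.0, np.where(dnmb < 0, 0.0, 0.5))))
        rows.append({"threshold": lam, f"p_{a}": p_a, f"p_{b}": 1.0 - p_a})
    return pd.DataFrame(rows)


def ce_plane(samples: pd.DataFrame, threshold: float) -> dict[str, float]:
    """Quadrant proportions of the incremental (effect, cost) cloud.

    Quadrants are named from the intervention's perspective:
    ``more_effective_cheaper`` (dominant), ``more_effective_costlier``,
    ``less_effective_cheaper``, ``less_effective_costlier`` (dominated).
    ``accept`` is the fraction of points below the threshold ray, i.e. with
    positive incremental net monetary benefit (ties counted half).
    """
    if len(samples) == 0:
        raise SensitivityError("no PSA samples")
    de = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    east = de > 0
    north = dc > 0
    n = float(len(samples))
    dnmb = threshold * de - dc
    return {
        "more_effective_cheaper": float(np.sum(east & ~north)) / n,
        "more_effective_costlier": float(np.sum(east & north)) / n,
        "less_effective_cheaper": float(np.sum(~east & ~north)) / n,
        "less_effective_costlier": float(np.sum(~east & north)) / n,
        "accept": float(
            np.mean(np.where(dnmb > 0, 1.0, np.where(dnmb < 0, 0.0, 0.5)))
        ),
    }


# -------------------------------------------------------------------- tornado


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the incremental result to a single parameter."""

    path: str
    base_input: float
    low_input: float
    high_input: float
    inc_cost_low: float
    inc_cost_high: float
    inc_nmb_low: float
    inc_nmb_high: float

    @property
    def width(self) -> float:
        return abs(self.inc_nmb_high - self.inc_nmb_low)

    @property
    def cost_width(self) -> float:
        return abs(self.inc_cost_high - self.inc_cost_low)


def default_tornado_paths(cfg: dict) -> list[str]:
    """Every cost subtotal and every utility, per arm and state."""
    paths = []
    for arm, spec in cfg["arms"].items():
        for s in LIVING_STATES:
            paths.append(f"arms.{arm}.utilities.{s}")
        paths.append(f"arms.{arm}.drug_cost")
        for s in LIVING_STATES:
            paths.append(f"arms.{arm}.other_costs.{s}")
    return paths


def tornado(
    cfg: dict,
    paths: list[str] | None = None,
    perturbation: float = 0.20,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Each parameter is set to base x (1 - p) and base x (1 + p) in turn,
    holding everything else at base case, and the full model is rerun.
    Perturbed utilities are clamped at 1 (with a warning) to stay in their
    domain.  The incremental cost and incremental net monetary benefit
    (intervention minus comparator, at the configured threshold) are
    recorded; entries are sorted by descending NMB bar width.  The NMB
    metric is reported alongside incremental cost because a negative
    base-case ICER is not rankable.
    """
    if paths is None:
        paths = default_tornado_paths(cfg)
    a_name, b_name = arm_names(cfg)
    lam = build_threshold(cfg).value

    def incremental(c: dict) -> tuple[float, float]:
        results, _ = evaluate_config(c)
        ra, rb = results[a_name], results[b_name]
        dc = ra.total_cost - rb.total_cost
        dnmb = (ra.total_qalys - rb.total_qalys) * lam - dc
        return dc, dnmb

    entries = []
    for path in paths:
        base_value = float(get_path(cfg, path))
        lo_hi = []
        for factor in (1.0 - perturbation, 1.0 + perturbation):
            value = base_value * factor
            if ".utilities." in path and value > 1.0:
                warnings.warn(
                    f"{path}: perturbed utility {value:.3f} clamped to 1.0",
                    stacklevel=2,
                )
                value = 1.0
            sub = _model_subset(cfg)
            set_path(sub, path, value)
            dc, dnmb = incremental(sub)
            lo_hi.append((value, dc, dnmb))
        (lv, lc, ln), (hv, hc, hn) = lo_hi
        entries.append(
            TornadoEntry(
                path=path,
                base_input=base_value,
                low_input=lv,
                high_input=hv,
                inc_cost_low=lc,
                inc_cost_high=hc,
                inc_nmb_low=ln,
                inc_nmb_high=hn,
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "base_input": e.base_input,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "inc_cost_low": e.inc_cost_low,
                "inc_cost_high": e.inc_cost_high,
                "inc_nmb_low": e.inc_nmb_low,
                "inc_nmb_high": e.inc_nmb_high,
                "nmb_width": e.width,
                "cost_width": e.cost_width,
            }
            for e in entries
        ]
    )


def psa_config_from(cfg: dict, seed: int, n_iterations: int | None = None) -> PSAConfig:
    """Assemble the default PSA configuration from a model config."""
    psa = cfg.get("psa", {})
    n = n_iterations if n_iterations is not None else int(psa.get("n_iterations", 5000))
    return PSAConfig(
        specs=tuple(default_psa_specs(cfg)),
        n_iterations=n,
        seed=seed,
        thresholds=tuple(threshold_grid(cfg)),
    )
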