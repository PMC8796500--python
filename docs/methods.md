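# Methods note

## Model structure

The decision model is a cohort state-transition (Markov) model with annual
cycles and a lifetime horizon. Living states are EDSS bands 0–2.5, 3–5.5
(relapsing-remitting phase, RRMS), 6–7.5 and 8–9.5 (secondary-progressive
phase, SPMS), plus absorbing death. The cohort enters at age 34, entirely in
EDSS 0–2.5, and is propagated to age 100 (66 cycles) or until surviving
mass falls below 1e-6, whichever comes first.

Transition evidence enters as a 4×4 table of percentages conditional on
survival together with a separate per-state annual death probability. Since
living rows already sum to ~100 %, they cannot be used verbatim next to the
death column; the composed matrix applies death first and distributes
survivors proportionally to the re-normalized living row:
`P(s→death)=d_s`, `P(s→j)=(1−d_s)·p_sj/Σ_k p_sk`. This preserves both the
printed conditional transition pattern and the printed death risks. Rows
summing to 100 ± 0.05 (one published row sums to 100.005) are re-normalized;
larger deviations are rejected rather than silently rescaled. Whether the
death column already includes background mortality is not stated in the
source evidence; it is used as the total annual death risk.

Rates are converted to per-cycle probabilities by `p = 1 − exp(−rt)`.

## Accrual and discounting conventions

Cycle-k accruals use start-of-cycle occupancy, so a cohort annihilated by
its first transition still accrues one cycle. The first cycle is
undiscounted (discount factor `(1+r)^−k` with k starting at 0); a
`discount_first_cycle` switch moves the exponent to k+1. No half-cycle
correction is applied by default (none is described for the source
analysis); it is available as a setting that averages start- and
end-of-cycle occupancy. Costs discount at 5.8 %/yr, outcomes (QALYs and
relapse counts) at 3 %/yr.

Relapses accrue only in the RRMS states, at the drug-specific annual
probability (rituximab 0.104, natalizumab 0.265), while therapy is active;
therapy and its acquisition cost stop on entry into SPMS. Relapses are a
counted outcome only — no relapse disutility or per-relapse cost feeds back
into the QALY or cost streams, matching the source analysis, which reports
relapses as a separate outcome alongside QALYs.

## Parameters

| Parameter | Value | Notes |
|---|---|---|
| Start age / horizon | 34 / 100 yr | annual cycles |
| Discount rates | 5.8 % costs, 3 % outcomes | |
| Threshold | 3 × GDP = $37,641/QALY | GDP $12,547 (2019) |
| RRMS utilities | 0.754/0.530 (natalizumab), 0.833/0.621 (rituximab) | EQ-5D-3L study means per band |
| Annual drug cost | $32,942.24 / $2,038.51 | charged in RRMS states only |
| Non-drug annual cost (RRMS) | $3,115.84 / $3,360.77 | observed total minus drug |
| SPMS utilities | 0.49 (EDSS 6–7.5), 0.20 (8–9.5) | **placeholder, not study data**; typical MS utility magnitudes, shared across arms |
| SPMS non-drug costs | $6,000 / $10,000 per yr | **placeholder, not study data**; care costs rising with disability, shared across arms |
| Cost PSA dispersion | CV 0.2 per cost parameter | **placeholder**; no cost SDs are published |

All monetary values are 2019 PPP$ (22,075 Rials per PPP$). Placeholders are
enumerated under `not_from_paper` in the bundled configuration and echoed
into every run manifest, so an audit of a run lists exactly which inputs are
assumptions. Because the SPMS placeholders are shared across arms, they
largely cancel in incremental cost and QALY; absolute lifetime totals do
depend on them, which is why this package validates the engine by
properties and oracles rather than by asserting the source analysis's
absolute totals.

## Sensitivity analysis

One-way analysis perturbs each cost and utility parameter by ±20 % (with
utilities clamped at 1), reruns the full model, and reports both the
incremental cost and the incremental net monetary benefit per bar, sorted by
NMB bar width. Incremental NMB is reported because the base-case ICER is
negative (dominance), and negative ICERs are not rankable.

The probabilistic analysis draws every utility from a beta distribution and
every cost parameter (drug cost and per-state non-drug cost, per arm) from a
gamma distribution, both parameterized by method of moments from mean and
SD — the standard choice when only first and second moments are reported.
Utilities are sampled independently per (arm, state); no correlation
structure is imposed. Transition probabilities are *not* sampled: parameter
uncertainty is confined to utility and cost inputs. Each of the 5000
iterations redraws all parameters and reruns the lifetime model per arm. A
master seed spawns one substream per iteration, so results are independent
of execution order and exactly reproducible. CEAC ties in net monetary
benefit are split 0.5/0.5 (a measure-zero event, handled explicitly for
determinism).

With Table-sized utility SDs (up to 0.186), the incremental QALY flips sign
in roughly a third of draws, which is why the CE plane shows a dominant-
quadrant share well below 1 while the CEAC at the threshold is ≈ 1: the
~30× cost gap dwarfs λ·ΔQALY in essentially every draw. Occasional extreme
utility draws (|ΔQALY| ≳ 6) can flip the NMB sign, so the acceptability at
the threshold computes to 99.9–100.0 % rather than exactly 100 %.

## Synthetic cohort

The generator emulates the study sample: 60 patients per arm, 74.17 %
female, ages Normal(33.4, 7.27) and Normal(34.92, 5.94) per arm truncated to
[18, 65] (the source is silent on bounds; truncation avoids implausible
draws), all patients enrolled in EDSS 0–2.5 by default (configurable to a
band mix so the 3–5.5 strata are exercised), and at least one year on drug
per the inclusion criterion.

Utility targets are realized indirectly so the scoring path is exercised: a
latent utility is drawn from a beta distribution moment-matched to the
target mean/SD on the value set's score range, then snapped to the EQ-5D-3L
code with the nearest score (ties to the lexicographically smallest code).
Relapse counts are Poisson with mean = target annual rate × years on drug;
years on drug are 1 + Exponential(mean 2 yr) truncated at 10 — minimal
distributional choices, as the source publishes none. Cost lines are annual
use count × unit price from the micro-costing menu with multiplicative
log-normal noise (σ = 0.10, mean 1); items whose yearly use "varies by
condition" enter as count 1 × observed mean. Indirect costs use
pre-computed human-capital amounts (observed means), as no wage inputs are
published.

The bundled EQ-5D-3L value set is synthetic (additive decrements, floor
−0.2) because the national time-trade-off tariff used in the source study is
not printed; any user value set loads from a 243-code table or a
coefficient file. Consequently, passing tests demonstrate that the
estimators recover the generator's targets through the real scoring path —
not that any particular national tariff is reproduced.

What the generator does not emulate: longitudinal EDSS trajectories
(the Markov model owns disease course), within-patient correlation between
utility, relapse and cost, non-response/recall error in self-reported
costs, and insurance heterogeneity (all patients insured).

## Numerical choices and verification

- Matrix composition is validated to row-stochasticity within 1e-12;
  occupancy conservation (living + cumulative dead = 1) holds to 1e-9 over
  the full horizon.
- The cohort engine is cross-checked against two independent oracles: exact
  matrix powers (start × Mⁿ, 1e-10) and a 200,000-path individual-level
  microsimulation (agreement within 3 Monte-Carlo SE).
- Method-of-moments beta/gamma fits are verified to reproduce input
  mean/SD exactly in closed form and within 1 % over 1e5 draws.
- Sample-size choices in the test suite: convergence checks use 100× the
  study arm size (6,000/arm) with tolerance max(1 % relative, 3 MC SE);
  the dominance-robustness PSA checks use 200 draws per setting.

## Limitations

- Absolute lifetime totals depend on the unpublished SPMS inputs and on
  cycle-timing conventions; only incremental conclusions are robust, and
  the package asserts exactly that.
- The base-case relapse totals depend on the accrual rule (RRMS-only,
  therapy-active); the source analysis's relapse totals imply an unstated
  rule and are not asserted.
- Two strategies only; no efficiency frontier, extended dominance, EVPI, or
  parameter correlation structure.
- Background mortality beyond the per-state death column (e.g. age-dependent
  life tables) is not modelled.
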