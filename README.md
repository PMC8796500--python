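# mscea

Lifetime Markov cohort cost-utility analysis of rituximab versus natalizumab
in relapsing-remitting multiple sclerosis (RRMS), from a societal
perspective, with all costs in 2019 purchasing-power-parity dollars (PPP$).

The package is aimed at health-economic modellers: it implements the full
pipeline of such an evaluation — synthesis of a patient-level study sample,
estimation of the model inputs from patient records (EQ-5D-3L utilities,
pooled relapse rates, micro-costed societal costs), an annual-cycle cohort
state-transition model over EDSS disability bands, incremental
cost-effectiveness analysis, and deterministic plus probabilistic
sensitivity analysis — as tested, reusable library code with a thin CLI.

## The model

Living health states are four EDSS bands (0–2.5, 3–5.5, 6–7.5, 8–9.5) plus
absorbing death. Patients enter at age 34 in EDSS 0–2.5 and transition
annually until age 100; entry into EDSS ≥ 6 marks secondary progression
(SPMS), at which point disease-modifying therapy and its acquisition cost
stop. Published transition evidence is given as conditional percentages
among survivors next to a separate per-state annual death probability, so
the 5×5 matrix is composed death-first:

    P(s → death) = d_s,   P(s → j) = (1 − d_s) · p_sj / Σ_k p_sk

Rates convert to per-cycle probabilities via `p = 1 − exp(−rt)`. Each cycle
accrues, from start-of-cycle occupancy: costs (annual drug cost while
therapy is active, plus per-state non-drug cost), QALYs (per-state
utilities), and expected relapses (drug-specific annual probability in the
RRMS states). Costs discount at 5.8 %/yr, outcomes at 3 %/yr. Two arms are
compared by incremental cost-effectiveness ratio (ICER) and net monetary
benefit (NMB = QALY × λ − cost) at the willingness-to-pay threshold
λ = 3 × GDP per capita = 3 × $12,547 = $37,641 per QALY.

Uncertainty is propagated two ways: a ±20 % one-way analysis of every cost
and utility parameter (tornado), and a 5000-iteration second-order
Monte-Carlo analysis with method-of-moments beta distributions on utilities
and gamma distributions on costs, summarized as a cost-effectiveness
acceptability curve (CEAC) and quadrant shares on the incremental
cost-effectiveness plane.

## Worked example

Run the whole pipeline on the bundled base-case configuration:

```sh
mscea -v all --seed 1 --out out/
```

which prints, among the stage logs:

```
INFO mscea: base case: rituximab dominant (delta cost -224072.92, delta QALY 0.7253)
INFO mscea: psa: rituximab cost-effective in 100.0% of draws at threshold 37641
```

and writes `out/base_case.csv`:

```
strategy,cost_ppp,qalys,relapses,life_years,nmb_ppp
natalizumab,305778.49,9.0557,2.3245,29.1127,35088.93
rituximab,81705.57,9.7811,0.9123,29.1127,286463.21
```

Reading: over a discounted lifetime, the rituximab strategy costs
PPP$ 81,706 and yields 9.78 QALYs and 0.91 expected relapses; natalizumab
costs PPP$ 305,778 for 9.06 QALYs and 2.32 relapses. Rituximab is therefore
*dominant* (cheaper and more effective; no ICER is reported for a dominant
comparison), `out/tornado.csv` shows the result is most sensitive to the
natalizumab drug price, and `out/ce_plane.csv` shows 66.8 % of Monte-Carlo
draws in the dominant quadrant with 99.98 % of draws below the threshold
ray. Secondary-progressive utilities and non-drug costs are not published
study inputs; the bundled config carries clearly-flagged placeholder values
(shared across arms, so they largely cancel in the increments), and the run
manifest logs every placeholder actually used. Absolute lifetime totals
therefore depend on those placeholders; the dominance verdict does not.

The same stages are available individually (`mscea synth`, `estimate`,
`model`, `cea`, `tornado`, `psa`) and as library functions.

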