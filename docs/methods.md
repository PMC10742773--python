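# Methods

## Model structure and assumptions

The model is a semi-Markov cohort simulation: state occupancy is tracked per
(state, time-in-state) so that tunnel states can force exits after a fixed
dwell time and state-entry survival fits can run on their own clock. Nine
states: front-line treatment, front-line remission ("disease_free"), salvage
chemotherapy (GDP: gemcitabine/dexamethasone/cisplatin), autologous
stem-cell transplant (SCT), post-SCT remission, CAR-T therapy, post-CAR-T
remission, palliative care, dead. The whole cohort starts in front-line
treatment at age 55 (midpoint of an adult cohort aged ≤60; configurable).

Key structural choices, all configurable:

* **Cycle grid.** 3-month cycles, 120 cycles (30 years). Rewards use a
  half-cycle correction (occupancy averaged over each cycle's two
  boundaries); discounting compounds the 1.5%/year rate per cycle,
  `(1+r)^(−0.25c)`.
* **Front line.** A two-cycle tunnel (≈ six 21-day chemotherapy cycles).
  Survivors without an event move to front-line remission. Adverse events
  (febrile neutropenia, nausea/vomiting) are a one-time probability per
  course (0.642 with ibrutinib, 0.303 without) that books a one-time cost
  and a one-cycle utility decrement in expectation, not a separate state.
* **EFS/OS decomposition.** In front-line states, per-cycle death comes
  from the arm's overall-survival Weibull and per-cycle events from its
  event-free-survival Weibull; relapse = events − deaths, clamped at zero
  (with a logged warning when the OS hazard exceeds the EFS hazard). The
  published fits do not state their time unit; **years** is the default
  (the slowest and only plausible reading; months or cycles would imply
  near-universal relapse within the first year) and is configurable.
* **Relapse plateau.** After five years (20 cycles) of sustained remission
  the relapse hazard is zero. The clock is model time for front-line
  remission and time-in-state for the post-SCT and post-CAR-T remission
  states. Mortality is never plateaued.
* **Salvage pathway.** Salvage response (0.3755/cycle, the midpoint of the
  published 0.300–0.451 range) sends patients to SCT. Non-responders
  progress at the GDP progression rate (PFS events minus GDP-OS deaths,
  time-in-state); progressors go to CAR-T (0.201) or palliation (0.393)
  with the residual continuing in progression. From SCT: 0.419/cycle to
  remission, 0.500/cycle to relapse (0.201 CAR-T / 0.393 palliation /
  residual continues). Relapse **out of a remission state** cannot stay
  put: 0.393 goes to palliation, the complement to CAR-T.
* **Ambiguous point-probability periods**, fixed once: post-SCT remission
  relapse (0.350, midpoint of 0.200–0.500) is cumulative over the 5-year
  at-risk window before the plateau; post-CAR-T remission death (0.059) is
  annual; salvage response and the SCT branch rows are per-cycle.
* **CAR-T delivery** is a two-cycle tunnel; survivors without progression
  move to post-CAR-T remission. **Palliation** lasts exactly two cycles
  (six months) and ends in death.
* **Background mortality** acts in every alive state as a competing hazard:
  within a cycle, background death applies first and survivors face the
  disease transitions, so combined death is `1 − (1−q_bg)(1−p_disease)` —
  exactly additive hazards for exponential competing risks (verified
  against a 10⁶-draw Monte-Carlo oracle in the tests).
* **Mortality attribution** (`mortality_mode`). Default `"pathway"`: each
  salvage-pathway state carries the death hazard of its own source fit.
  Alternative `"os_anchored"`: the arm's intention-to-treat OS curve drives
  disease death in all non-palliative states, avoiding the double counting
  that arises because an ITT OS fit already contains post-relapse deaths.
  The default keeps the literal per-state sourcing; the switch exists
  because neither attribution can be read off the published tables.

## Economics

Costs are 2022 CAD from a public-payer perspective. QALYs weight life-years
by per-state utilities on the 0 (death) – 1 (perfect health) scale. For a
fixed cohort trace both totals are *linear* in the table entries; the
`economics.reward_loadings` coefficients make that linearity explicit and
are reused by the calibration, so accumulation and calibration cannot
drift apart numerically. One-time costs are discounted at the entry cycle.
Incremental analysis sorts strategies by cost, removes strictly dominated
ones, applies extended dominance, and reports ICERs between frontier
neighbors; undefined ratios are reported as dominance, never as numbers.

## Synthetic inputs and calibration

Per-state costs, utilities and the background life table are not published;
`synthetic_data` generates stand-ins (every artifact stamped SYNTHETIC):

* **Life table.** Gompertz–Makeham hazard `h(a) = c + b·e^{g·a}` with
  defaults (c = 3·10⁻⁴, b = 1.8·10⁻⁵ /y, g = 0.087 /y) chosen so a healthy
  55-year-old has ≈72% 30-year survival — the right order of magnitude for
  a general high-income population, not an official table.
* **Cost/utility tables.** Drawn from documented plausible 2022-CAD ranges
  with the orderings built in: CAR-T ≫ transplant ≫ chemotherapy for
  one-time costs; remission utilities above treatment-state utilities above
  palliation (≈0.80–0.93 remission, 0.50–0.75 active treatment, 0.15–0.45
  palliation). The two arms differ only in the front-line per-cycle cost
  (ibrutinib rides on top of R-CHOP).
* **Calibration.** Matching published per-strategy totals is a bounded
  linear least-squares problem (two equations per quantity, many unknowns),
  solved with BVLS plus a weak regularization toward a seeded plausible
  start — the solution is deliberately the *nearest plausible* table, and
  only the achieved outputs are guaranteed, not the recovered parameters.
  Lower bounds on the one-time CAR-T/transplant costs are search bounds,
  not asserted prices (negotiated Canadian prices are confidential).
  Infeasible targets (QALY above the model's life-years) and residuals
  beyond tolerance fail loudly; `strict=False` returns the best-achievable
  tables with `converged=False` and full residuals.

### Why the published QALY totals cannot be matched

Life-years are fixed by the transition structure, not by costs or
utilities, and QALY ≤ LY always. The discounted life-year ceiling of the
comparator arm from its overall-survival Weibull *alone* — utility 1
everywhere, no background mortality, no pathway mortality — is

∫₀³⁰ exp(−0.081·t^0.769) · 1.015^(−t) dt = 14.08 years,

already below the published comparator QALY total of 14.245 (the
undiscounted integral, 16.80, is likewise below the published 17.59
life-years). Faster time units only lower the ceiling. The published
survival parameterization and the published totals are therefore mutually
inconsistent as printed; no cost/utility table can close the gap.
Calibration consequently reproduces the published **cost** totals exactly
(42,085.59 CAD incremental cost), drives the QALYs to their structural
ceiling (residual ≈ −20%, reported), and the resulting base-case ICER
(≈33,800 CAD/QALY) sits at the published magnitude because the achieved
QALY gap (≈1.24) matches the published 1.234 closely. The corresponding
acceptance test records the QALY residual as a failure by design rather
than loosening the check.

## Sensitivity analyses

* **PSA.** Every flat parameter gets a moment-matched distribution — beta
  for probabilities and utilities, gamma for costs, lognormal for Weibull
  parameters (the conventional choices) — with standard error defaulting to
  10% of the mean because input uncertainties are not published (a stand-in
  consistent with the ±10% one-way interrogation). Parameters are drawn
  independently; both strategies share each draw (common random numbers),
  so incremental quantities are paired. Draws producing non-finite outcomes
  are excluded and counted. The CEAC reports the fraction of draws in which
  each strategy has maximal net monetary benefit, ties split equally.
* **DSA.** One-way ±10% on the probability scale with clamping to valid
  domains (probabilities/utilities to [0, 1]); Weibull shape/rate pairs are
  excluded from the default set because a ±10% move of a shape parameter is
  not a 10% move of any probability. Entries whose perturbation makes the
  comparison degenerate (dominance or an invalid configuration) are flagged,
  not dropped. The tornado sorts by descending ICER range, ties broken
  alphabetically.

## Problem sizes and numerics

Default analyses run the full 120-cycle horizon. The test suite uses 200
probabilistic draws on the full model (binomial error at p ≈ 0.75 is ±0.03,
ample for the directional CEAC check), 10⁵ draws on a closed-form toy model,
10⁶ draws for the competing-risk oracle, and 500 randomized configurations
for the engine invariants. Occupancy conservation is asserted to 1e-9,
row-stochasticity to 1e-12, and the telescoping identity between per-cycle
probabilities and the closed-form survival to 1e-10. Survival underflow
(S(t) = 0) returns a per-cycle probability of 1 with a logged warning; the
relapse clamp (OS events exceeding EFS events) logs the affected cycles.

## Limitations

* Cost/utility inputs are synthetic; absolute cost and QALY levels carry no
  evidential weight beyond their calibration targets. Conclusions should be
  read as properties of the model structure plus published transition
  parameters.
* The published survival parameterizations' time unit is asserted nowhere;
  years is a documented default, not the authors' confirmed intent.
* Parameters are drawn independently in the PSA; no correlation structure
  is published, though the interface accepts per-parameter bounds and could
  host one.
* The branching of salvage non-responders among CAR-T, palliation and
  continued progression is under-determined by the published rows; the
  renormalizations used are documented configuration, not asserted intent.
* A passing test suite shows internal consistency with the synthetic study
  conditions, not agreement with real-world Canadian cost-effectiveness.
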