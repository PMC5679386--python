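# Methods

## Model structure

`radcea` implements an annual-cycle Markov cohort model of a single
treatment decision: breast-conserving surgery followed by either
intraoperative radiation therapy (IORT) or ~6 weeks of whole-breast external
beam radiation therapy (EBRT), for a cohort of middle-aged women with
early-stage ER+ breast cancer and a complication-free life expectancy of 23
years.

Each strategy is a set of health states with annual costs, one-time entry
and dwell-exit (last-year-of-life) costs, and utilities in [0, 1]:

| state | utility | dwell (years) | exits to |
| --- | --- | --- | --- |
| well (complication-free) | 0.92 | 23 | dead |
| local/regional recurrence | 0.60* | 10 | dead |
| metastatic disease | 0.45* | 5.625 | dead |
| comorbid decline | 0.50* | 6.05 | dead |
| long-term complication (pooled) | 0.30* | 16 (IORT) / 14 (EBRT) | dead |
| dead | 0 | — | — |

Values marked * are calibration values (see below); the others are study
inputs. The comorbid dwell is the midpoint of the reported 4.2–7.9-year
range, with the range reserved for sensitivity sweeps. A state's life
expectancy is enforced by tunnel expansion: a dwell of *D* years becomes
⌈D⌉ state copies, the final copy weighting utility, annual cost and
life-years by frac(*D*), so the expected dwell of an entrant is exactly *D*
(5.625 → 6 copies, the last at weight 0.625).

Transitions out of the well state:

- **Years 0–10**: a composite recurrence-or-death event with 10-year
  cumulative probability 23% (IORT) / 25.4% (EBRT), spread uniformly on the
  hazard scale (p_annual = 1 − (1 − p_cum)^(1/10)) and split across
  destination states by shares of the log-survival, so the composite
  cumulative probability is honoured exactly regardless of the split.
- **Years 10–23**: the pooled long-term-complication transition. Its
  cumulative probability comes from the organ dose profile (below).

The acute phase applies at cycle 0 as expected one-time quantities:
procedure cost, probability × complication cost, and probability ×
complication disutility (a one-time QALY decrement). Rewards accrue to
state membership at cycle start; transitions happen at cycle end; there is
no half-cycle correction by default (an `EconomicSettings` flag switches
rewards to the average of start- and end-of-cycle occupancy, making the
choice testable).

## Radiation dose weighting

Mean organ doses are 5 Gy (heart), 3.8 Gy (ipsilateral lung) and 1.1 Gy
(contralateral breast) for EBRT versus 1.25, 0.03 and 0 Gy for IORT. Dose
maps to late-complication probability linearly with no threshold,
pᵢ = min(1, βᵢdᵢ), matching the linear excess-rate framing of the
radio-epidemiology this class of model draws on. The per-Gy coefficients
are calibration values chosen so that (i) the IORT pooled probability is
exactly 0.31% and (ii) the EBRT/IORT pooled ratio is exactly 15, the two
anchors the analysis reports. The three complications — major coronary
events, lung cancer, contralateral breast cancer — are pooled into a single
state whose dwell, entry cost, annual cost and last-year cost are
incidence-weighted means of per-complication components; component life
expectancies are set so the pooled dwell is exactly 16 years under IORT
doses and 14 under EBRT doses.

## Economics

Willingness to pay is $50,000/QALY. Costs are discounted at 3%/year.
Utilities are aggregated undiscounted in the study fixture: the reported
lifetime QALY totals (17.86 and 17.06) exceed the arithmetic maximum
attainable under 3%/year utility discounting with a 23-year well-state life
expectancy at utility 0.92 (0.92 × Σₜ₌₀²² 1.03⁻ᵗ ≈ 15.58), so the reported
results are only consistent with undiscounted utilities. The engine
supports separate cost and utility discount rates; analysts who want
symmetric 3% discounting set one field.

The simulation horizon is 80 cycles. The 23-year complication-free life
expectancy is encoded as the well state's dwell limit rather than as a hard
simulation stop, because conditions entered late (a long-term complication
at year 20 with a 14–16-year life expectancy; metastatic sweeps up to ~60
years) outlive year 23 by construction; 80 cycles is long enough that no
dwell tail or sweep is truncated. `total_qalys ≤ life_years ≤ horizon`
holds throughout.

## Calibration of unpublished parameters

The source analysis prints its anchors (cycle lengths, the 10-year event
probabilities, the 0.31% complication probability, doses, WTP, discounting,
the well utility 0.92) but not its full parameter appendix (state costs,
non-well utilities, the event-destination mix, acute-phase parameters).
Those are free calibration parameters here, **not** study facts. They were
fitted once, offline, and frozen as literals in `radcea.synthetic`:

1. plausible values were fixed for the non-well utilities, state costs and
   the per-arm destination mix (EBRT weighted more toward metastatic
   disease and late death, consistent with the excess non-breast-cancer
   mortality reported for external-beam irradiation);
2. because lifetime totals are linear in every cost and utility parameter,
   the two remaining degrees of freedom per arm — procedure cost and acute
   complication disutility — were solved in closed form so the lifetime
   totals equal the reported $53,179 / 17.86 QALYs (IORT) and
   $63,828 / 17.06 QALYs (EBRT).

With this calibration the model reproduces the reported cost/QALY values
($2,978 and $3,741), IORT dominance, the NMB ranking, and one-way threshold
flips on the same side of baseline as reported: the EBRT event probability
flips preference at ~18.7% (reported "< 19%"), the IORT event probability
at ~29.8% (reported "> 30%"), the metastatic life expectancy at ~45 years
(reported "> 51 years"), the IORT complication probability only far above
baseline (reported "> 24%"), and no well-utility value above 0 flips the
preference (reported "0"). Threshold *locations* other than the two event
probabilities depend on the unpublished costs and are not calibration
targets; only existence and direction are asserted in the tests.

## Sensitivity analysis

Parameters are addressed by dotted config paths
(`strategies.IORT.states.well.utility`); a tuple of paths sets several
scalars together, which is how a utility shared by both arms is swept. One-
way sweeps evaluate the full pipeline at equally spaced values. The tornado
ranks ranges by the NMB spread of the baseline-preferred strategy.
Threshold search scans 64 equally spaced points for sign changes of the NMB
difference (preferred strategy minus best competitor), then bisects a
single bracket to a width of 1e-6 × (high − low) by default; zero sign
changes return "none in range", several raise an ambiguity error listing
the brackets. The complication-probability sweep uses a risk-scale
multiplier on the dose-derived probabilities, so the dose→risk→pooled-state
chain stays intact during the sweep.

## Numerical choices

- Cycle length is fixed at 1 year; the cohort is a dense occupancy vector;
  transition matrices are cached per set of active windowed rules.
- Dwell durations within 1e-9 of an integer are snapped to it, so a derived
  pooled life expectancy of 16 ± 1e-15 cannot oscillate between 16 and 17
  tunnel copies across a parameter sweep.
- Exit-probability mass is validated statically (per window breakpoint) and
  re-checked each cycle at runtime; occupancy conservation is enforced to
  1e-9 and holds to machine precision in tests.
- A cumulative probability of 1 under extreme sweeps is capped at 1 − 1e-12
  before annualization (a cumulative probability of exactly 1 has no finite
  annual hazard).
- Entry costs are charged to flow entering a state from a *different*
  state (tunnel advancement and self-loops are not entries); last-year
  costs are charged to the dwell-exit flow; mass still in a state when the
  horizon ends incurs no exit cost.

## What the synthetic generator does and does not emulate

`study_fixture()` reproduces the *structure and anchors* of the source
analysis plus a committed calibration; `random_model(seed, n)` generates
arbitrary valid strategies (renormalized exit probabilities, one absorbing
dead state) for property tests; `closed_form_toy` builds two-state models
with analytic QALY totals as engine oracles. None of these carry real
patient-level heterogeneity, age-dependent background mortality, parameter
uncertainty (no probabilistic sensitivity analysis, matching the one-way
scope of the source), or real cost data — passing tests show the engine and
decision layer are correct and that the committed calibration reproduces
the reported analysis, not that the calibrated values are the true
unpublished ones.

## Known limitations

- Cohort fractions only; no individual-level microsimulation.
- Costs are undated USD; any inflation adjustment is pre-processing.
- The dose→risk map is linear with a hard clamp at 1; no age or latency
  structure within the late window.
- The event-destination mix and all non-anchored costs/utilities are
  calibration values; analyses that depend on their absolute levels (rather
  than the calibrated totals) should treat them as placeholders and supply
  their own configuration.
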