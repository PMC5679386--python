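# radcea

Lifetime Markov cohort cost-effectiveness analysis of adjuvant radiotherapy
strategies for early-stage breast cancer, with radiation-dose-weighted
long-term complications.

After breast-conserving surgery, patients may receive a single session of
intraoperative radiation therapy (IORT) or ~6 weeks of whole-breast external
beam radiation therapy (EBRT). The two strategies differ in upfront cost, in
recurrence outcomes, and — because EBRT delivers several times the incidental
organ dose (heart, ipsilateral lung, contralateral breast) — in the long-term
risk of major coronary events and second cancers. `radcea` is a config-driven
package for health economists and HTA analysts that simulates an annual-cycle
cohort over the patient's remaining lifetime and compares strategies by
dominance, cost per QALY, and net monetary benefit, with one-way sensitivity
and threshold analysis.

## Model

For each strategy, a cohort starts fully in a "well" (complication-free)
state after surgery plus radiation. Each annual cycle *t* the occupancy
vector **x**ₜ accrues rewards and then transitions:

- discounted cost: ∑ₜ xₜᵀc / (1+r_c)ᵗ, plus one-time entry, dwell-exit
  (last-year-of-life) and acute-phase costs;
- discounted QALYs: ∑ₜ xₜᵀu / (1+r_u)ᵗ, utilities u ∈ [0,1];
- states with a life expectancy *D* (e.g. 5.625 years for metastatic disease)
  are expanded into ⌈D⌉ tunnel copies, the last carrying fractional weight
  frac(D), so the expected dwell is exactly *D*;
- cumulative probabilities over a window (e.g. a 10-year cumulative
  recurrence-or-death probability) are spread on the hazard scale:
  p_annual = 1 − (1 − p_cum)^(1/w);
- organ doses d (Gy) map linearly to late-complication probabilities
  pᵢ = min(1, βᵢ dᵢ) (linear no-threshold), and the three complications
  (major coronary events, lung cancer, contralateral breast cancer) are
  pooled into one state whose life expectancy and costs are
  incidence-weighted means.

Strategies are compared by dominance (cheaper *and* more effective),
cost/QALY, the ICER for genuine trade-offs, and net monetary benefit
NMB = QALYs × WTP − cost at a willingness to pay of $50,000/QALY. Threshold
analysis bisects the NMB difference to find the parameter value at which the
preferred strategy flips.

## Worked example

```python
from radcea import CostEffectivenessAnalysis, study_fixture

model = CostEffectivenessAnalysis(study_fixture())   # or .from_file("config.yaml")
results = model.fit()
print(results.summary())
```

```
Cost-effectiveness comparison
================================================================
willingness to pay: $50,000/QALY   horizon: 80 years
discount rates: costs 3.0%/yr, utilities 0.0%/yr
----------------------------------------------------------------
Alternative  Direct cost  QALYs  Cost/QALY    NMB
       IORT        53179  17.86       2978 839821
       EBRT        63828  17.06       3741 789172
----------------------------------------------------------------
classification (IORT vs EBRT): dominant
preferred by NMB: IORT
```

IORT is *dominant*: it costs $10,649 less over the patient's lifetime and
yields 0.80 more quality-adjusted life years, so it also has the higher net
monetary benefit at $50,000/QALY. A threshold search shows how robust this
is — for example, the EBRT 10-year event probability would have to fall from
25.4% to below ~18.7% before EBRT became preferred:

```python
res = results.threshold("strategies.EBRT.event_risk.cumulative", (0.05, 0.254))
print(res.threshold)        # ~0.187; EBRT preferred below, IORT above
```

The same objects drive one-way sweeps (`results.one_way`), tornado diagrams
(`results.tornado`, `results.plot_tornado`) and report bundles
(`radcea.reporting.run_analysis`). A CLI mirrors the library:

```bash
radcea fixture --out study.yaml
radcea validate study.yaml
radcea run --config study.yaml --out reports/
radcea budget --cases 60000 --saving 10500 --indirect-delta 1520
```

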