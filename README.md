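# oncostruct

Structural comparison of the economic-model architectures used in oncology
health-technology assessment: the **partitioned survival model (PSM)**, a
**3-state semi-Markov cohort model** (progression-free / post-progression /
death, "STM3"), and a **5-state extension** that splits off brain-metastasis
health states ("STM5": PF / PP / BM with continuing initial therapy, BMIT / BM
with subsequent therapy, BMST / death).

The package targets the second-line EGFR-mutated NSCLC setting — an
osimertinib-like arm "A" versus a pemetrexed–platinum-like arm "B" — where
patients on the CNS-penetrant drug often continue initial therapy after brain
metastasis. A three-state model books that time as ordinary progression-free
survival; a five-state model books it in BM states with much lower utilities.
The question the pipeline answers is how much that structural choice moves the
incremental life-years (LY) and quality-adjusted life-years (QALY) between the
arms.

Because real claims data of this kind cannot be shared, the package ships a
**synthetic claims generator** that emulates the extraction: per-arm
cause-specific hazards on the five-state graph, administrative censoring, a
claims-based BM diagnosis rule (≥1 inpatient or ≥2 outpatient C793 claims),
baseline age/sex covariates and greedy 1:1 propensity matching.

## Methods in brief

- Ten right-censored endpoints are derived from observable events only
  (therapy switch, BM diagnosis, death): OS, TTNT (a PFS proxy), death
  before/after switch, and the BM-conditioned refinements driving the 5-state
  model.
- Each endpoint × arm is fitted independently by censored maximum likelihood
  over six families — exponential, Weibull, Gompertz, lognormal, log-logistic,
  generalized gamma (μ, σ, Q) — with AIC selection (AICc/BIC reported,
  proportional-hazards diagnostics via Cox/Schoenfeld).
- PSM occupancy is read off the curves (dead = 1 − S_OS, PF = min(S_TTNT,
  S_OS), PP = difference). The STMs advance a cohort in 21-day cycles with
  time-dependent transition probabilities q = 1 − S(t+c)/S(t), tunnel states
  tracking time-in-state for PP/BMIT/BMST, and a hazard-split rule for
  competing exits. A 200,000-individual microsimulation oracle validates the
  cohort engines.
- Outcomes: trapezoidal AUC over the cycle grid, continuous discounting at
  4.5%/yr, 7-year horizon; per-state and incremental LY/QALY; one-way
  sensitivity on horizon (5/10 y), rate (3/7.5%) and utility sets.

## Worked example

```bash
python analysis/01_simulate_cohorts.py   # cohorts, claims, matching, endpoints
python analysis/02_fit_survival.py       # six-family fits + AIC selection
python analysis/03_build_traces.py       # PSM / STM3 / STM5 occupancy traces
python analysis/04_summarize_outcomes.py # discounted LY/QALY + sensitivity
```

On the default scenario (735 patients/arm after matching, seed 20240209) the
final step prints:

```
incremental outcomes (arm A - arm B), discounted at 4.5%/yr over 7 years:
  PSM   incremental LY  1.256   incremental QALY  1.071
  STM3  incremental LY  1.264   incremental QALY  1.079
  STM5  incremental LY  1.255   incremental QALY  0.855

relative differences of incremental QALY (rounded %):
  STM5 vs PSM: -20%
  STM5 vs STM3: -21%
```

Read: the three structures agree on incremental survival (within 1% here),
but adding low-utility brain-metastasis states cuts the incremental QALY by
about a fifth — arm A's survival advantage is partly lived out in BM states,
which the three-state structures credit at full PF/PP utility.

## Layout

```
src/oncostruct/
  synthesize.py   cohort generator, claims rule, endpoints, matching
  families.py     the six parametric survival families
  fitting.py      KM, censored MLE, IC selection, PH diagnostics
  engines.py      PSM/STM3/STM5 traces, tunnel states, microsimulation
  outcomes.py     AUC, discounting, LY/QALY summaries, sensitivity grid
  pipeline.py     staged orchestration, comparison report, manifest
analysis/         numbered drivers for the four stages
docs/methods.md   modelling assumptions, parameter choices, limitations
```
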