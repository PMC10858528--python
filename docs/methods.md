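# Methods

## The decision problem and the three structures

All three models describe a cohort of second-line EGFR-mutated NSCLC patients
from the start of second-line therapy (the index date) over a 7-year horizon
in 21-day cycles, and report discounted life-years (LY) and quality-adjusted
life-years (QALY) per arm plus incrementals (arm A − arm B).

**PSM.** State occupancy is read directly off two survival curves: dead =
1 − S_OS(t); progression-free = min(S_TTNT, S_OS); post-progression = the
difference. TTNT (time to next treatment or death) proxies PFS because claims
data record therapy switches, not progression. Where the fitted TTNT curve
crosses above OS, PF is capped at OS (PP floored at 0) and the cap is logged.

**STM3.** A semi-Markov cohort model on {PF, PP, Death}. Per cycle, PF exits
by death with q₂ = 1 − S_d(t+c)/S_d(t) from the death-before-switch curve on
the model-time clock, and by progression with q₁ = (total PF exit from the
TTNT curve) − q₂, floored at 0 (floor activations are counted and surfaced —
they signal inconsistent extrapolations). PP is expanded into tunnel layers
indexed by time-since-entry; each layer dies with the death-after-switch
curve evaluated on the time-in-state clock.

**STM5.** Adds BMIT and BMST. Patients with baseline BM history start in
BMIT; the rest start in PF. PF has three competing exits (progression, death,
BM); PP has two (death, BM); BMIT has two (therapy switch, death); BMST dies
by its own curve. PP, BMIT and BMST are all tunnelled; BMIT→BMST entrants
restart the BMST clock.

**Competing exits.** Cause-specific conditional exit probabilities are
combined by a hazard-split: each qᵢ becomes a cycle hazard λᵢ = −ln(1−qᵢ),
the total exit is 1 − exp(−Σλᵢ), allocated ∝ λᵢ. This guarantees Σp ≤ 1 for
arbitrary curves and is exact when one cause is active. Because the TTNT
curves already count death ("next treatment **or** death"), the (TTNT, death)
pair is first reduced to an effective total exit with a death share, and only
then combined with the BM cause; this makes STM5 collapse *exactly* (to
1e-12) onto STM3 when BM hazards and the baseline-BM fraction are zero. A
plain-subtraction rule (probabilities used as-is, rescaled past 1) is
available via `competing="subtraction"`; the two differ at O(c²).

**Why one cap/floor per construct is kept visible.** The floor on q₁ and the
PSM min-cap both fire only when independently fitted curves disagree about
the same underlying quantity; their activation counts appear in trace
warnings and the run manifest because the structural comparison is only
interpretable when such corrections are rare.

## Endpoints are defined on observable events

A claims extraction observes three things per patient: the first next-line
therapy date, the BM diagnosis date (the claims rule below), and death. All
ten endpoints are defined in those terms, never via latent disease states:

| endpoint | clock | at risk | event | censors |
|---|---|---|---|---|
| os | index | all | death | cut-off |
| ttnt | index | all | switch or death | cut-off |
| death_from_pf | index | all | death before any switch | switch, cut-off |
| death_from_pp | switch | switched | death | cut-off |
| ttnt_from_pf | index | no BM history | switch or death | BM diagnosis, cut-off |
| bm_from_pf | index | no BM history | BM diagnosis | switch, death, cut-off |
| bm_from_pp | switch | switched, no prior BM | BM diagnosis | death, cut-off |
| ttnt_in_bmit | BM diagnosis | diagnosed pre-switch | switch or death | cut-off |
| death_in_bmit | BM diagnosis | diagnosed pre-switch | death | switch, cut-off |
| death_in_bmst | max(diagnosis, switch) | both observed | death | cut-off |

The three-state model's "PF" is simply *pre-switch* (it has no BM concept),
so `death_from_pf`/`death_from_pp` partition every observed death — the
property that makes STM3's mortality complete. The five-state model reuses
those two shared curves for its PF/PP death exits; they are mildly
contaminated by BM-state person-time, a compromise inherent in driving two
structures from one endpoint set, and second-order at the shipped BM rates.

**BM diagnosis rule.** A patient is diagnosed at the earliest date at which
they have ≥1 inpatient C793 claim or ≥2 outpatient C793 claims (date of the
second). The generator emits qualifying patterns for true BM events
(inpatient with probability 0.5, otherwise two outpatient claims 7 days
apart), truncated at death/censoring — so near-cut-off events can evade
diagnosis, as in real claims — plus a single non-qualifying outpatient claim
for 5% of never-BM patients.

## The synthetic scenario

Latent times are drawn per state entry (clocks restart: semi-Markov) from
per-edge, per-arm distributions; the transition taken is the competing
minimum, with BM winning exact ties. Defaults, all exponential (rates /day):

| edge | arm A | arm B | anchor |
|---|---|---|---|
| PF→PP (next treatment) | 0.0012 | 0.0033 | A's switch-or-death median ≈ 16 mo vs ≈ 6 mo for B |
| PF→Death | 0.0003 | 0.0006 | minority of deaths occur before any next line |
| PF→BMIT | 0.0007 | 0.0007 | CNS progression risk similar at baseline |
| PP→Death | 0.0019 | 0.0028 | ~1 y post-progression survival, worse on B |
| PP→BMST | 0.0004 | 0.0005 | BM after switch is less common |
| BMIT→BMST (switch) | 0.0010 | 0.0045 | A continues initial therapy through BM; B switches fast |
| BMIT→Death | 0.0008 | 0.0025 | A survives much longer with BM |
| BMST→Death | 0.0030 | 0.0060 | ditto after the switch |

Covariates: 61.5% female, age ~ N(64.9, 9.5²), identical across arms (the
matched design); 20% baseline BM history; 735 patients per arm. Index dates
are uniform over 3 years with the cut-off 2,200 days after the earliest
index, giving 3–6 years of potential follow-up. The window is deliberately
long relative to the horizon: with very short follow-up the three structures'
LY comparison is dominated by parametric-tail noise rather than structure,
and mortality is nearly completely observed here (>95% of arm-B deaths).

Utilities: PF 0.800 (A) / 0.730 (B); BMIT 0.520 shared; progressed states
carry a 0.042 decrement (PP 0.758/0.688, BMST 0.478). Discount rate 4.5%/yr.

**What the generator does not emulate:** treatment-pattern covariates beyond
age/sex (so matching is near-trivial by construction), time-varying hazards
within a state beyond the optional Weibull edges, diagnosis-coding error
other than the single-claim noise, competing non-cancer mortality, and any
cost accrual. Passing tests therefore demonstrate internal validity of the
machinery and the structural mechanism — not calibration to any real cohort.

## Fitting and selection

Censored MLE maximizes Σ_events log f + Σ_censored log S by Nelder-Mead from
several starting points (moment-based; five sign-spanning starts for
Gompertz, four Q-starts for the generalized gamma), with a plausibility box
on internal parameters (σ ≳ 0.02, |Q| ≤ 5, |Gompertz shape| ≤ 1/day, scales
within e±15) that prevents the σ→0 likelihood spike of location-scale
families. The generalized gamma uses the (μ, σ, Q) form with S expressed via
regularized incomplete gamma functions and an explicit lognormal branch at
|Q| < 1e-6; Q = 1 reproduces the Weibull exactly, which the tests exploit.
Negative Gompertz shapes (plateauing survival) are allowed and reported.

Selection: lowest AIC among converged fits (AICc and BIC are reported; ties
break toward fewer parameters, then a fixed family order); an explicit
per-endpoint override stands in for visual inspection. Endpoints with zero
events get a flat null curve (zero-rate exponential) with a warning.
Proportional hazards are tested per endpoint (Cox fit on the arm indicator,
scaled Schoenfeld trend test, log-cumulative-hazard curves) for diagnostics
only — all endpoints are fitted independently per arm.

## Numerical conventions

- Days internally; 1 year = 365.25 days; cycle c = 21 days; horizon 7 y →
  ⌈2556.75/21⌉ = 122 cycles, occupancy recorded at boundaries 0, c, …, 122c.
- Tunnel depth equals the full horizon (no truncation).
- LY/QALY integrate occupancy by trapezoid on the cycle grid (equivalent to a
  half-cycle correction), applied uniformly to all three structures;
  discounting is continuous inside the integrand, (1+r)^(−t/365.25), which
  differs from a per-cycle step factor by <0.1% at 21-day cycles and has
  closed-form test oracles.
- Curves numerically exhausted (S < 1e-300) exit the whole remaining cohort.
- Same-day progression and BM route to BMIT (BM precedence, a deterministic
  tie-break for a measure-zero event).
- The microsimulation oracle advances integer counts per (state, tunnel
  layer) with multinomial draws using exactly the cohort engine's per-cycle
  probabilities — distributionally identical to simulating individuals
  one-by-one and fast enough for n = 200,000 checks.
- One global seed fans out to named substreams (generation, claims) so later
  stages never perturb earlier ones; every stage reads and writes plain CSV/
  JSON, so any stage can be re-run from disk.

## Test problem sizes

The suite favors exact oracles (closed forms, matrix powers of the one-cycle
transition matrix, quadrature over hazards) at sizes chosen for a single CPU:
parameter recovery uses 20 replicates at n = 2,000 with 20% administrative
censoring; selection-consistency 12 replicates at n = 800; PH null
calibration 60 replicates and power 10 replicates at n = 800/arm;
conservation 100 random curve configurations; oracle equivalence one
200,000-individual microsimulation per structure; the end-to-end structural
check one full 735-per-arm study.

## Known limitations

- The incremental results depend on the synthetic scenario; only the
  *pattern* (LY agreement across structures, QALY depression under the
  five-state structure) is a designed property, verified across seeds.
- The shared death curves blur the five-state model's PF/PP mortality
  slightly, as discussed above.
- Matching is demonstrative: with identical covariate laws across arms there
  is no confounding to remove.
- No costs, ICERs or probabilistic sensitivity analysis; one-way sensitivity
  only.
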