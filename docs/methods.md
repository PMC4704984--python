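# Methods

This note documents the model implemented by `steppedcare`: its structure and
assumptions, the parameter conventions, the reconstruction choices that were
genuinely open, the numerical conventions, and what the synthetic-data
machinery does and does not establish.

## 1. Decision problem and states

Three strategies for an adult presenting in primary care with a
mild-to-moderate depressive episode: the myCompass internet CBT program,
face-to-face CBT, and antidepressant treatment-as-usual (TAU). Health states
are *episode*, *remission* and *maintenance*; remission and maintenance share
one utility weight, so the state space reduces to episode vs
remission/maintenance for QALY purposes. The horizon is 28 weeks in four
7-week cycles (one acute cycle, three maintenance cycles); no discounting is
applied at this horizon. The perspective is the Australian health provider
(Medicare + PBS), direct costs only — productivity and other societal costs
are out of scope by design.

## 2. Tree structure

The published tree is only partially specified, so the package fixes one
documented topology (`src/steppedcare/data/topology.yaml`, user-overridable
via the `topology` block of a config). Per arm:

1. **Acute phase (cycle 1, episode state).** Patients are non-adherent with
   the arm's acute non-adherence probability; adherent patients respond
   (transition to remission at the end of cycle 1) with the arm's initial
   effect size.
2. **Step-up switch.** Acute non-adherers and adherent non-responders switch
   to antidepressants for the remaining cycles (stepped care). The switch is
   resolved over cycle 2: remitters spend cycles 3–4 in maintenance; failures
   discontinue and remain in the episode state.
3. **Maintenance phase (cycles 2–4) for responders.** The maintenance effect
   size and maintenance non-adherence are each applied once over the 21-week
   phase (the input table lists single per-arm maintenance values, not
   per-cycle ones). 40% of maintenance non-adherers return to treatment and
   then face the same sustain/relapse split as adherers; the remaining 60%
   discontinue. Relapse is detected at the end of the first maintenance
   cycle: relapsers occupy maintenance for cycle 2 and episode for cycles
   3–4. Discontinuers are conservatively assigned the episode state (and
   episode utility) for all remaining weeks.

Transitions occur at cycle boundaries with no half-cycle correction — the
simplest convention consistent with a 7-week acute program. Each arm unrolls
to nine root-to-terminal paths; branch probabilities are expressions over
named parameters and are checked to sum to one at every chance node.

**Remission after the switch.** The published inputs give a remission
probability on *second-line* antidepressants (0.306 — a second drug after a
failed first drug) and a remission probability after switching from CBT
(0.585). For switchers out of the myCompass arm the package uses the
*first-line* antidepressant effect (0.462): those patients have never been
exposed to medication, and the model's stated assumption is that success
rates are independent of previous treatment exposure. This assignment is
load-bearing: it is what makes the internet-CBT arm's QALYs exceed TAU's
despite its higher non-adherence, reproducing the published strategy ordering
(CBT > myCompass > TAU in QALYs; myCompass optimal on NMB). Treating
myCompass switchers as second-line (0.306) instead makes TAU weakly dominant
— an outcome inconsistent with every published summary of this comparison.
The topology file makes the alternative a one-line edit.

## 3. Costs

Costs are inner products of per-path resource tallies with fixed unit costs
(AUD 2013/14): GP mental-health plan 71.70, standard GP consultation 36.88,
psychiatrist consultation 367.80, psychologist session 141.87, CBT course
737.72, myCompass delivery 56.39 (12-month cost, charged once).

* Every arm incurs the mental-health plan, one closing GP review, and an
  expected 0.056 psychiatrist consultations for the presenting episode.
* **GP visit streams** (2.48 visits per episode cycle, 1.89 per
  remission/maintenance cycle) accrue during clinician-managed cycles only:
  cycles on antidepressants (TAU, or post-switch in any arm), on face-to-face
  CBT or boosters, and post-remission GP monitoring in those arms. Cycles
  spent on the fully automated myCompass program generate no GP stream (the
  program is designed to be used without clinician consultation; its GP
  contact is the plan and the closing review), and discontinued patients
  generate no further resource use. This rule reproduces the signature
  published cost pattern — a cheap, low-variance myCompass arm against an
  expensive TAU arm — and is the package's main costing reconstruction.
* **Non-completion.** Acute-phase non-completers incur a configurable
  fraction (`completion_fraction`, default 0.5) of the acute intervention
  cost. This is a reconstruction of the statement that treatment costs were
  adjusted for non-completers; the fraction is deliberately exposed as a
  parameter.
* **Medication.** The per-cycle antidepressant cost was never published (only
  described as the PBS average of the least and most costly commonly
  prescribed antidepressants). `cost_medication_per_cycle` defaults to
  AUD 60.00 — roughly AUD 37 per 28-day script scaled to 7 weeks — and is
  flagged as a **placeholder**. The qualitative results (strategy ordering at
  the base case, the λ=0 acceptability result, myCompass optimal at
  AUD 50,000/QALY) hold for medication costs anywhere from 0 to at least
  AUD 150 per cycle, but absolute TAU costs move with it.
* CBT maintenance boosters are monthly sessions, carried as
  `booster_sessions_per_cycle` = 7×12/52 ≈ 1.615 sessions per cycle.

## 4. Parameters and distributions

Probabilities carry Beta(events, non-events) distributions and utilities
Beta distributions matched to published moments; one switch-remission
probability is lognormal(−0.713, 0.188) on the log scale. Conventions:

* **Point estimates vs distribution means.** Base-case runs use the published
  point estimates verbatim; the PSA samples the published distributions. For
  most Beta rows α/(α+β) reproduces the printed point estimate at 3 dp
  (0.374, 0.349, 0.306, 0.163, 0.279, 0.336, 0.184, 0.486); a few differ in
  the third decimal (0.462 vs 0.4636, 0.479 vs 0.4774, 0.222 vs 0.2226), and
  the lognormal row's printed 0.585 matches neither the lognormal mean
  (≈0.499) nor median (≈0.490). Both values are stored; neither is silently
  recomputed from the other.
* **Bounds.** Draws for probability/utility parameters are confined to
  [0, 1]; the lognormal is truncated by resampling (rejection), which leaves
  in-range quantiles undistorted. Unit costs and resource counts are fixed in
  the PSA (no published cost distributions exist); one-way analysis varies
  them instead.
* **Random numbers.** One root seed; each parameter draws from a substream
  keyed by a stable hash of its name, so adding or removing a parameter never
  reshuffles the others' draws. Within a PSA iteration the same parameter set
  is applied to all three strategies (common random numbers).
* Effect sizes are interpreted as probabilities of transition to the
  remission state (the source trial's remission criterion, DASS < 27).

## 5. PSA, CEAC and sensitivity analysis

The PSA default is 10,000 iterations (evaluated vectorised through the path
enumeration, well under a second). Summaries use means and equal-tailed
empirical 2.5/97.5 percentiles without smoothing. The CEAC winner per
iteration is the argmax of NMB with ties broken by lowest cost, then
declaration order — relevant only for degenerate configurations, but it keeps
the curve deterministic. The default λ grid is 0 to 100,000 in steps of
1,000, covering both decision landmarks (50,000 and 65,000).

One-way analysis is deterministic (all other parameters at point estimates),
default 101 grid points; the shipped sweep brackets for the three headline
parameters are the published ones (myCompass non-adherence 0–0.35, CBT
delivery cost 0–619, myCompass delivery cost 0–564). Threshold analysis
scans the bracket at 101 points for a change of optimum and refines the
crossing by bisection to 0.01 in the parameter's units. In the default
reconstruction the optimum never changes over the non-adherence bracket,
face-to-face CBT displaces myCompass when a CBT course becomes cheap enough,
and the myCompass delivery cost can rise several-fold before the optimum
changes — the same qualitative pattern as published, though the exact
crossing values are structure-dependent.

## 6. Value of information

Per-patient EVPI is computed directly from the PSA draws
(E[max_s NMB] − max_s E[NMB], clamped for float-epsilon negatives), with a
500-resample bootstrap standard error. EVPPI uses nested Monte Carlo (outer
draws of the target parameter × inner joint draws of the rest; defaults
1,000 × 1,000, tunable) or, alternatively, a single-loop regression estimator
(cubic polynomial smoothing of per-draw NMB on the target parameter) with the
same contract; the two agree on an analytically tractable two-strategy toy
model. Population scaling multiplies per-patient value by
(0.25 + 0.59) × 0.206 × 4.4 million × 2% acceptability × 1 year, exactly the
published extrapolation formula.

**Where the decision uncertainty lives.** In this reconstruction the EVPPI is
carried almost entirely by the health-state utilities — above all the
moderate-episode utility, whose published Beta(0.88, 0.65) has a standard
deviation of ≈0.31 and regularly reverses the episode-vs-maintenance utility
gap that CBT's extra remission time is paid with. The myCompass acute
non-adherence rate, by contrast, has EVPPI numerically zero: under its
published Beta(201, 519) (sd ≈ 0.017) the adoption decision is insensitive to
it — the NMB margin of the myCompass arm moves by only ≈ −3 AUD per 0.01 of
non-adherence, so a decision flip would require values above ≈0.8 that the
distribution never produces. The original analysis reported the opposite
attribution (non-adherence the only parameter with positive EVPPI); that
attribution cannot be reproduced from the published distributions, and the
corresponding acceptance test documents the discrepancy rather than masking
it.

## 7. Synthetic data and what the tests show

The microsimulation walks individual patients down the same declarative trees
(sampling each chance node) and realises fractional expected resource counts
as Poisson draws with the stated mean, so its empirical means converge to the
cohort expectations — the oracle-equivalence tests compare the two at
n = 200,000 within three Monte-Carlo standard errors. The synthetic-trial
generator emulates the Bernoulli outcomes behind the Beta(events, non-events)
rows and closes the probability → trial → refitted-Beta recovery loop.

This machinery validates the *internal* consistency of the pipeline: that
enumeration, simulation, sampling and summarisation agree, and that the
published deterministic arithmetic is reproduced. It does not emulate
patient-level heterogeneity beyond tree branching, within-cycle event timing,
item-level symptom data, or correlation between parameters — so passing tests
say nothing about how the model would fit richer real-world data.

## 8. Numerical conventions and problem sizes

Branch-probability sums are enforced to 1e−12 at build (point estimates) and
1e−9 at evaluation; the NMB identity is exact arithmetic; credible intervals
use linear-interpolation percentiles; reports round currency to 2 dp,
probabilities to 3 dp, thresholds to 2 dp. Default problem sizes — 10,000 PSA
iterations, 200,000 microsimulation patients for oracle comparisons,
1,000 × 1,000 nested EVPPI (300–500 per side for parameter ranking) — were
chosen so that Monte-Carlo error is negligible relative to every decision
margin the analysis reports.

## 9. Known limitations

* The tree topology and costing rules beyond the published narrative are
  reconstructions; absolute cost/QALY levels (and hence printed ICERs,
  credible intervals and threshold values) are calibration-sensitive and are
  deliberately not test targets. Published mean QALYs (0.24–0.29 over
  28 weeks) lie below the floor attainable from the published utilities
  (≈0.31 with all time in episode), so the original QALY accounting is not
  recoverable in principle.
* Severity mix affects utilities only, not costs or transition probabilities.
* No combination therapy, no re-treatment after relapse, no adverse-event
  utility decrements, no Markov extension beyond the unrolled four cycles.
* The medication unit cost is a placeholder (Section 3).
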