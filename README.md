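# steppedcare

Cost-utility decision modelling for **stepped care in mild-to-moderate
depression**: a 28-week, three-arm cohort decision tree comparing an
internet-delivered CBT program (myCompass) used as the first step of care,
face-to-face cognitive behaviour therapy (CBT), and antidepressant
treatment-as-usual (TAU), from the perspective of the Australian health
provider (Medicare/PBS, AUD 2013/14).

The package is aimed at health economists and methods researchers who want a
fully scripted, testable re-implementation of this style of analysis — every
input is a named parameter with a point estimate and an uncertainty
distribution, the tree topology is a plain-text file, and each pipeline stage
(deterministic roll-back, probabilistic sensitivity analysis, acceptability
curves, one-way/threshold analysis, value-of-information) is a library
function with a thin CLI on top.

## The model

Patients start in a depressive **episode** and receive 7 weeks of acute
treatment in their assigned arm. Responders enter **remission** and a 21-week
**maintenance** phase (maintenance medication, monthly CBT boosters, or the
myCompass booster program), with maintenance non-adherence, return-to-treatment
and relapse risks. Acute non-adherers and non-responders step up to
antidepressants for the remaining cycles; switch failures discontinue. The
4×7-week horizon is unrolled into a finite tree and evaluated by exhaustive
path enumeration.

Outcomes per strategy *s* are expected cost *C_s* (resource counts × unit
costs) and expected QALYs *E_s* (weeks in each state × state utility / 52,
with the episode utility mixed over symptom severity: 0.688·u_moderate +
0.312·u_mild). Strategies are compared with

- net monetary benefit **NMB_s(λ) = E_s·λ − C_s** at willingness-to-pay λ
  (default λ = AUD 50,000/QALY); the optimal strategy maximises NMB;
- **ICER = ΔC/ΔE** and the average cost-effectiveness ratio C/E;
- the **CEAC**: P(strategy has highest NMB) across λ, from a 10,000-iteration
  PSA over the published Beta/lognormal parameter distributions;
- **EVPI / EVPPI**: E_θ[max_s NMB_s(θ)] − max_s E_θ[NMB_s(θ)], per patient and
  scaled to the eligible Australian population.

A patient-level microsimulation of the same trees acts as an independent
brute-force oracle for the cohort expectations.

> **Note:** the antidepressant unit cost per 7-week cycle was not published;
> the packaged value of `cost_medication_per_cycle` (AUD 60) is a documented
> placeholder. See `docs/methods.md` before relying on absolute TAU costs.

## Worked example

```sh
steppedcare make-config              # writes the packaged input tables
steppedcare base-case                # deterministic roll-back
```

```
 strategy  cost_aud   qaly  nmb_at_wtp
      TAU    487.32 0.3752    18271.38
      CBT   1281.27 0.3918    18310.85
myCompass    361.18 0.3783    18556.27
```

At the published point estimates myCompass is the cheapest arm (AUD 361.18),
CBT yields the most QALYs (0.3918), and myCompass has the highest net monetary
benefit at AUD 50,000/QALY — it *dominates* TAU (cheaper and more effective)
and displaces CBT because CBT's extra 0.0135 QALYs cost AUD 920 more.

```sh
steppedcare ceac                     # 10,000-iteration PSA + CEAC
# P(highest NMB) at wtp=50000: {'TAU': 0.073, 'CBT': 0.254, 'myCompass': 0.672}

steppedcare threshold --param cost_mycompass --range 0:564
# cost_mycompass: optimum changes from myCompass to CBT at 341.60

steppedcare voi
# EVPI  estimate_aud 140.30  (per patient, AUD, at wtp 50000)
```

Under parameter uncertainty myCompass is the most likely optimum at the
AUD 50,000 threshold (67% of iterations; CBT takes over as λ grows), its
delivery cost could rise roughly six-fold (to ≈ AUD 342) before it stops being
optimal, and perfect information on all parameters would be worth about
AUD 140 per treated patient.

All subcommands accept `--config`, `--seed`, `--out DIR` and write CSV tables
plus a YAML run manifest (config hash, seeds, iteration counts, version) that
makes every output reproducible bit-for-bit.

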