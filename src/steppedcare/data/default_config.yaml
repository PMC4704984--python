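# Default model configuration: the published input tables for the three-arm
# stepped-care depression model (myCompass internet CBT vs face-to-face CBT vs
# antidepressant treatment-as-usual), 28-week horizon, Australian provider
# perspective, AUD 2013/14.
#
# Beta distributions are (events, non-events); lognormal is (mu, sigma) on the
# log scale.  Base-case runs use point_estimate as printed; PSA samples the
# distribution.  cost_medication_per_cycle is a documented PLACEHOLDER — see
# docs/methods.md before relying on absolute TAU costs.
strategy_names: [TAU, CBT, myCompass]
cycle_length_weeks: 7
n_cycles: 4
weeks_per_year: 52
wtp_default: 50000.0
severity_mix:
  moderate: 0.688
  mild: 0.312
psa_iterations: 10000
rng_seed: 2013
parameters:
  eff_initial_tau:
    role: probability
    point_estimate: 0.462
    distribution: {kind: beta, args: [121.0, 140.0]}
    source_note: "Initial effect size, antidepressants; review of clinical trials"
  eff_initial_cbt:
    role: probability
    point_estimate: 0.479
    distribution: {kind: beta, args: [127.0, 139.0]}
    source_note: "Initial effect size, face-to-face CBT; review of CBT clinical trials"
  eff_initial_mycompass:
    role: probability
    point_estimate: 0.449
    distribution: {kind: beta, args: [202.0, 247.0]}
    source_note: "Initial effect size, myCompass; RCT data"
  eff_maintenance_tau:
    role: probability
    point_estimate: 0.374
    distribution: {kind: beta, args: [1075.0, 1801.0]}
    source_note: "Maintenance effect size, antidepressants; clinical trial data"
  eff_maintenance_cbt:
    role: probability
    point_estimate: 0.559
    distribution: {kind: beta, args: [146.0, 115.0]}
    source_note: "Maintenance effect size, CBT; meta-analysis of CBT clinical trials"
  eff_maintenance_mycompass:
    role: probability
    point_estimate: 0.349
    distribution: {kind: beta, args: [122.0, 228.0]}
    source_note: "Maintenance effect size, myCompass at follow-up; RCT data"
  return_to_treatment:
    role: probability
    point_estimate: 0.4
    distribution: {kind: fixed}
    source_note: "Probability that a maintenance non-adherer returns to treatment"
  remission_second_line:
    role: probability
    point_estimate: 0.306
    distribution: {kind: beta, args: [440.0, 999.0]}
    source_note: "Remission on second-line antidepressants after a failed first antidepressant; clinical trial data"
  remission_switch_cbt:
    role: probability
    point_estimate: 0.585
    distribution: {kind: lognormal, args: [-0.713, 0.188]}
    source_note: "Remission after switching to antidepressants following CBT; meta-analysis (lognormal on log scale, truncated to [0,1] when sampled)"
  nonadherence_acute_tau:
    role: probability
    point_estimate: 0.163
    distribution: {kind: beta, args: [599.0, 3072.0]}
    source_note: "Acute-phase non-adherence, antidepressants; clinical trial data"
  nonadherence_acute_cbt:
    role: probability
    point_estimate: 0.222
    distribution: {kind: beta, args: [59.0, 206.0]}
    source_note: "Acute-phase non-adherence, CBT; review of clinical trial data"
  nonadherence_acute_mycompass:
    role: probability
    point_estimate: 0.279
    distribution: {kind: beta, args: [201.0, 519.0]}
    source_note: "Acute-phase non-adherence, myCompass; RCT data"
  nonadherence_maintenance_tau:
    role: probability
    point_estimate: 0.336
    distribution: {kind: beta, args: [1436.0, 2839.0]}
    source_note: "Maintenance non-adherence, antidepressants; retrospective database analysis"
  nonadherence_maintenance_cbt:
    role: probability
    point_estimate: 0.184
    distribution: {kind: beta, args: [962.0, 4268.0]}
    source_note: "Maintenance non-adherence, CBT boosters; meta-analysis of discontinuation trials"
  nonadherence_maintenance_mycompass:
    role: probability
    point_estimate: 0.486
    distribution: {kind: beta, args: [350.0, 370.0]}
    source_note: "Maintenance non-adherence, myCompass at follow-up; RCT data"
  utility_mild:
    role: utility
    point_estimate: 0.78
    distribution: {kind: beta, args: [15.74, 4.44]}
    source_note: "Health-state utility, mild depressive episode"
  utility_moderate:
    role: utility
    point_estimate: 0.58
    distribution: {kind: beta, args: [0.88, 0.65]}
    source_note: "Health-state utility, moderate depressive episode"
  utility_maintenance:
    role: utility
    point_estimate: 0.88
    distribution: {kind: beta, args: [1.44, 0.19]}
    source_note: "Health-state utility, remission/maintenance"
  gp_visits_episode:
    role: resource-count
    point_estimate: 2.48
    distribution: {kind: fixed}
    source_note: "GP visits per 7-week cycle in the episode state; longitudinal database analysis"
  gp_visits_remission:
    role: resource-count
    point_estimate: 1.89
    distribution: {kind: fixed}
    source_note: "GP visits per 7-week cycle in remission/maintenance; longitudinal database analysis"
  psychiatrist_visits_episode:
    role: resource-count
    point_estimate: 0.056
    distribution: {kind: fixed}
    source_note: "Psychiatrist consultations per depressive episode; population survey data"
  booster_sessions_per_cycle:
    role: resource-count
    point_estimate: 1.6154
    distribution: {kind: fixed}
    source_note: "Monthly CBT booster sessions expressed per 7-week cycle (7 x 12/52); reconstruction convention"
  cost_gp_plan:
    role: unit-cost
    point_estimate: 71.70
    distribution: {kind: fixed}
    source_note: "GP mental health plan (initial + review), MBS items 2700/2712, AUD"
  cost_gp_consultation:
    role: unit-cost
    point_estimate: 36.88
    distribution: {kind: fixed}
    source_note: "Standard GP consultation, MBS items 3/23, AUD"
  cost_psychiatrist:
    role: unit-cost
    point_estimate: 367.80
    distribution: {kind: fixed}
    source_note: "Psychiatric consultation, MBS items 291/293, AUD"
  cost_psychologist_session:
    role: unit-cost
    point_estimate: 141.87
    distribution: {kind: fixed}
    source_note: "Single psychologist session, weighted average of MBS items 80000/80010, AUD"
  cost_cbt_course:
    role: unit-cost
    point_estimate: 737.72
    distribution: {kind: fixed}
    source_note: "Course of face-to-face CBT (weighted session cost x average sessions attended), AUD"
  cost_mycompass:
    role: unit-cost
    point_estimate: 56.39
    distribution: {kind: fixed}
    source_note: "myCompass delivery cost per user (12-month budgeted delivery), AUD"
  cost_medication_per_cycle:
    role: unit-cost
    point_estimate: 60.00
    distribution: {kind: fixed}
    source_note: "PLACEHOLDER antidepressant cost per 7-week cycle (PBS midpoint of least/most costly common antidepressants); not published — see docs/methods.md"
  completion_fraction:
    role: scaling-constant
    point_estimate: 0.5
    distribution: {kind: fixed}
    bounds: [0.0, 1.0]
    source_note: "Fraction of acute-phase intervention cost incurred by non-completers; reconstruction convention"
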