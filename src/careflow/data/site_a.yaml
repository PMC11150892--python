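# Synthetic profile "site_a": the larger of the two packaged sites, with
# longer treatment waits and heavier waiting-list attrition.  Routing and
# wait medians were chosen so the abstracted flows sit near the rates a
# large stepped-care talking-therapies service reports (roughly one third
# of referrals discharged before assessment, ~21% discharged at triage,
# step-2/step-3 waiting-list attrition near 24%/32%, stepped care ~3%,
# total-wait medians ~13 weeks for the step-2 route and ~34 weeks for the
# step-3 route).  Waiting times are log-normal (right-skewed, median well
# below the mean); medians are in weeks.
site_name: site_a
n_cases: 45401
seed: 11
window:
  start: 2019-06-01
  end: 2021-06-01
routing:
  post_referral: {proceed: 0.86, discharge: 0.14}
  assessment_waitlist: {proceed: 0.785, discharge: 0.215}
  post_assessment: {step2: 0.455, step3: 0.335, discharge: 0.21}
  step2_waitlist: {proceed: 0.76, discharge: 0.24}
  step2_treatment: {proceed: 0.80, step_up: 0.20}
  step3_waitlist: {proceed: 0.68, discharge: 0.32}
  step3_treatment: {proceed: 1.0}
wait_dists:
  referral_to_discharge: {family: lognormal, median: 1.0, sigma: 0.8}
  referral_to_assessment_wl: {family: lognormal, median: 0.15, sigma: 0.5}
  assessment_wl_to_assessment: {family: lognormal, median: 4.0, sigma: 0.6}
  assessment_wl_to_discharge: {family: lognormal, median: 7.0, sigma: 0.6}
  assessment_to_discharge: {family: lognormal, median: 1.0, sigma: 0.5}
  assessment_to_step2_wl: {family: lognormal, median: 0.3, sigma: 0.5}
  assessment_to_step3_wl: {family: lognormal, median: 0.3, sigma: 0.5}
  step2_wl_to_treatment: {family: lognormal, median: 9.0, sigma: 0.6}
  step2_wl_to_discharge: {family: lognormal, median: 16.6, sigma: 0.6}
  step3_wl_to_treatment: {family: lognormal, median: 30.0, sigma: 0.5}
  step3_wl_to_discharge: {family: lognormal, median: 38.0, sigma: 0.5}
  stepup_to_step3_wl: {family: lognormal, median: 0.3, sigma: 0.5}
  treatment_to_discharge_planning: {family: lognormal, median: 1.0, sigma: 0.4}
  discharge_planning_to_discharge: {family: lognormal, median: 0.3, sigma: 0.4}
sessions:
  step2: {family: poisson_shifted, lam: 5.0, shift: 1}
  step3: {family: poisson_shifted, lam: 7.0, shift: 1}
  before_stepup: {family: poisson_shifted, lam: 2.0, shift: 1}
  gap_weeks: {family: lognormal, median: 1.0, sigma: 0.3}
attendance_prob: 0.895
attendance_missing_rate: 0.004
outcome_model:
  pre_score_mean: 16.0
  pre_score_sd: 5.0
  caseness_threshold: 10.0
  completeness: 0.95
  recovery_prob: {step2: 0.50, step3: 0.46, stepped: 0.48}
corruption:
  rate: 0.019
  magnitude: {family: lognormal, median: 2.3, sigma: 1.0}
attributes:
  age: {median: 31.0, sigma: 0.45}
  gender: {female: 0.6664, male: 0.3289, nonbinary: 0.0042, unspecified: 0.0005}
  presenting_problem:
    anxiety: 0.3189
    depression: 0.2665
    other_mental_health: 0.0277
    other_recorded: 0.0031
    unspecified: 0.3838
  referral_source: {self: 0.9449, gp: 0.0315, other: 0.0236}
  prior_referrals: {"0": 0.8470, "1": 0.1123, "2": 0.0407}
  imd_deciles: [0.1058, 0.1115, 0.0931, 0.1092, 0.0902, 0.0905, 0.1217, 0.0881, 0.0820, 0.1079]
  imd_missing_rate: 0.0046
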