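# Synthetic profile "site_b": smaller sister site with shorter waits, less
# waiting-list attrition, a higher triage-discharge rate, a higher missed-
# appointment rate, better recovery, and a noisier record system (a larger
# share of back-dated timestamps with smaller offsets).
site_name: site_b
n_cases: 12590
seed: 12
window:
  start: 2019-06-01
  end: 2021-06-01
routing:
  post_referral: {proceed: 0.93, discharge: 0.07}
  assessment_waitlist: {proceed: 0.877, discharge: 0.123}
  post_assessment: {step2: 0.41, step3: 0.294, discharge: 0.296}
  step2_waitlist: {proceed: 0.81, discharge: 0.19}
  step2_treatment: {proceed: 0.80, step_up: 0.20}
  step3_waitlist: {proceed: 0.76, discharge: 0.24}
  step3_treatment: {proceed: 1.0}
wait_dists:
  referral_to_discharge: {family: lognormal, median: 0.8, sigma: 0.8}
  referral_to_assessment_wl: {family: lognormal, median: 0.15, sigma: 0.5}
  assessment_wl_to_assessment: {family: lognormal, median: 3.0, sigma: 0.6}
  assessment_wl_to_discharge: {family: lognormal, median: 5.0, sigma: 0.6}
  assessment_to_discharge: {family: lognormal, median: 0.8, sigma: 0.5}
  assessment_to_step2_wl: {family: lognormal, median: 0.3, sigma: 0.5}
  assessment_to_step3_wl: {family: lognormal, median: 0.3, sigma: 0.5}
  step2_wl_to_treatment: {family: lognormal, median: 5.0, sigma: 0.6}
  step2_wl_to_discharge: {family: lognormal, median: 10.0, sigma: 0.6}
  step3_wl_to_treatment: {family: lognormal, median: 18.0, sigma: 0.5}
  step3_wl_to_discharge: {family: lognormal, median: 23.8, sigma: 0.5}
  stepup_to_step3_wl: {family: lognormal, median: 0.3, sigma: 0.5}
  treatment_to_discharge_planning: {family: lognormal, median: 1.0, sigma: 0.4}
  discharge_planning_to_discharge: {family: lognormal, median: 0.3, sigma: 0.4}
sessions:
  step2: {family: poisson_shifted, lam: 4.0, shift: 1}
  step3: {family: poisson_shifted, lam: 6.0, shift: 1}
  before_stepup: {family: poisson_shifted, lam: 2.0, shift: 1}
  gap_weeks: {family: lognormal, median: 1.0, sigma: 0.3}
attendance_prob: 0.882
attendance_missing_rate: 0.0011
outcome_model:
  pre_score_mean: 16.0
  pre_score_sd: 5.0
  caseness_threshold: 10.0
  completeness: 0.964
  recovery_prob: {step2: 0.54, step3: 0.50, stepped: 0.52}
corruption:
  rate: 0.072
  magnitude: {family: lognormal, median: 0.5, sigma: 1.0}
attributes:
  age: {median: 35.0, sigma: 0.42}
  gender: {female: 0.6496, male: 0.3494, nonbinary: 0.0005, unspecified: 0.0005}
  presenting_problem:
    anxiety: 0.3553
    depression: 0.3449
    other_mental_health: 0.0241
    other_recorded: 0.0066
    unspecified: 0.2691
  referral_source: {self: 0.7826, gp: 0.0689, other: 0.1485}
  prior_referrals: {"0": 0.8020, "1": 0.1488, "2": 0.0492}
  imd_deciles: [0.1005, 0.1063, 0.1658, 0.1084, 0.0627, 0.0983, 0.0863, 0.0543, 0.0951, 0.1223]
  imd_missing_rate: 0.0022
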