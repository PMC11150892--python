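# Abstraction level B: as level A but treatment stages are pooled into
# step-level subprocesses and waiting-list events are RETAINED (they are
# what makes waiting-list attrition visible in route analysis).
name: B
rename_map:
  "Referral received": referral_received
  "Assessment waiting list": assessment_waitlist
  "Waiting list (assessment)": assessment_waitlist
  "Assessment": assessment
  "Initial assessment (v1)": assessment
  "Step 2 waiting list": step2_waitlist
  "Guided self-help": step2_gsh
  "Guided self-help (old)": step2_gsh
  "Computerised CBT": step2_ccbt
  "Step 3 waiting list": step3_waitlist
  "CBT": step3_cbt
  "CBT (v1)": step3_cbt
  "Counselling": step3_counselling
  "EMDR": step3_emdr
  "Step change": step_change
  "Discharge planning": discharge_planning
  "Discharged": discharged
subprocess_groups:
  discharged: [discharge_planning, discharged]
  step2_treatment: [step2_gsh, step2_ccbt]
  step3_treatment: [step3_cbt, step3_counselling, step3_emdr]
exclusions: [step_change]
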