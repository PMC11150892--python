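# Abstraction level A: canonical stage names, discharge planning collapsed
# into the discharge stage, waiting-list and administrative events excluded.
# Individual treatment stages are kept, giving the process-map view.
name: A
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
exclusions: [assessment_waitlist, step2_waitlist, step3_waitlist, step_change]
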