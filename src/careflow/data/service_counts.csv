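site,quantity,numerator,denominator,value
site1,referrals_received,,,45401
site1,completion,18058,45401,
site1,recovery,8212,17151,
site1,recovery_data_completeness,17151,18058,
site1,missed_appointments,21757,206564,
site1,events_adjusted,6491,336637,
site1,map_coverage,43183,45401,
site1,immediate_discharge,14659,43183,
site1,post_assessment_discharge_of_assessed,5935,28524,
site1,post_assessment_discharge_of_covered,5935,43183,
site1,post_assessment_discharge_of_all,5970,45401,
site1,pretreatment_attrition_of_triaged,6193,22589,
site1,pretreatment_attrition_step2,3124,13003,
site1,pretreatment_attrition_step3,3069,9586,
site1,pretreatment_attrition_of_covered,6193,43183,
site1,assessment_wl_attrition,8437,45401,
site1,stepped_common,1117,,
site1,stepped_uncommon,390,,
site1,stepped_total,1507,45401,
site1,step2_treated_wait_median,,,13.3
site1,step2_attrition_wait_median,,,20.6
site1,step3_treated_wait_median,,,34
site1,step3_attrition_wait_median,,,41.9
site2,referrals_received,,,12590
site2,completion,5220,12590,
site2,recovery,2632,5034,
site2,recovery_data_completeness,5034,5220,
site2,missed_appointments,6524,55415,
site2,events_adjusted,8921,123523,
site2,assessment_wl_attrition,1442,12590,
site2,post_assessment_discharge_of_all,3035,12590,
site2,stepped_common,365,,
site2,stepped_uncommon,162,,
site2,stepped_total,527,12590,
site2,step2_treated_wait_median,,,8.1
site2,step2_attrition_wait_median,,,13.1
site2,step3_treated_wait_median,,,21
site2,step3_attrition_wait_median,,,26.8
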