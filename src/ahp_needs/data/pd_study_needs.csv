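need_id,category_id,group_gw,group_lw,median_technical_gw,median_technical_lw,median_clinical_gw,median_clinical_lw,gw_ttest_p,lw_ttest_p
motor_symptoms_assessment,performance,0.064,0.292,0.064,0.304,0.032,0.231,0.522,0.486
on_off_fluctuations_detection,performance,0.085,0.388,0.099,0.392,0.078,0.288,0.269,0.24
cognitive_behavioral_assessment,performance,0.042,0.197,0.030,0.127,0.041,0.305,0.844,0.032
data_mining_disease_modelling,performance,0.028,0.129,0.027,0.090,0.024,0.120,0.448,0.664
increase_wearability_acceptance,user_experience,0.102,0.457,0.077,0.388,0.068,0.461,0.782,0.494
user_friendly_interfaces,user_experience,0.068,0.305,0.077,0.281,0.047,0.310,0.849,0.408
seamlessly_integration,user_experience,0.053,0.237,0.038,0.322,0.026,0.169,0.099,0.107
increase_patient_clinician_bond,clinical_practice,0.054,0.181,0.041,0.203,0.048,0.139,0.695,0.736
increase_patient_carers_knowledge,clinical_practice,0.080,0.270,0.054,0.25,0.063,0.245,0.761,0.593
increase_self_management_support,clinical_practice,0.093,0.314,0.058,0.290,0.089,0.284,0.880,0.849
increase_assist_care_givers,clinical_practice,0.070,0.235,0.051,0.201,0.062,0.259,0.482,0.814
decrease_visits_and_stays_in_hospital,economic,0.022,0.175,0.015,0.169,0.027,0.162,0.313,0.588
increase_patient_quality_of_life,economic,0.063,0.511,0.051,0.468,0.035,0.376,0.826,0.197
faster_and_more_reliable_diagnosis,economic,0.039,0.313,0.029,0.299,0.050,0.323,0.189,0.428
scalability_and_interoperability,technical_issues,0.040,0.293,0.039,0.310,0.026,0.281,0.472,0.615
security_and_privacy,technical_issues,0.059,0.430,0.041,0.464,0.029,0.396,0.563,0.600
decrease_maintenance_and_support_cost,technical_issues,0.038,0.277,0.024,0.177,0.049,0.367,0.092,0.341
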