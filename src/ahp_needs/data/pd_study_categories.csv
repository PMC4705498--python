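category_id,cw,median_technical_cw,median_clinical_cw,ttest_p
performance,0.219,0.207,0.200,0.375
user_experience,0.222,0.216,0.159,0.560
clinical_practice,0.297,0.233,0.278,0.573
economic,0.124,0.110,0.104,0.520
technical_issues,0.137,0.103,0.140,0.337
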