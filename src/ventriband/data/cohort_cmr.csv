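patient,gender,age_yr,weight_kg,p_rv_max_mmhg,rv_edv_ml,rv_esv_ml,rv_ef_pct,pvr_delta_ef_pct
P1,M,22.5,80,31.4,406.91,254.49,37.5,1.49
P2,M,47.7,95,31,408.76,254.79,37.7,-2.56
P3,M,43.5,123,65,665.06,464.05,30.2,-15.22
P4,F,38.5,49,28,328.79,195.97,40.4,-3.35
P5,M,11.6,38,36,204.17,121.26,40.6,-8.41
P6,F,14.3,58.5,29,204.00,104.30,48.8,5.57
P7,F,44.6,57.1,50,299.00,186.00,37.8,-12.32
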