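exposure_h,role,concentration_mg_ml,tcc,tcd,mi_percent,mi_sd,ca_percent,ca_sd,m_inh_percent,mf,mf_sd
24,negative_control,0,3000,756,25.20,0.31,0.53,0.15,,0.02,0.00
24,combined,21.5,3000,436,14.53,0.12,6.57,0.41,35.12,0.45,0.00
24,combined,43,3000,430,14.33,0.18,7.27,0.50,24.37,0.53,0.01
24,combined,64.5,3000,395,13.17,0.16,7.77,0.25,22.22,0.59,0.01
24,positive_control,4,3000,310,10.33,0.44,9.83,0.19,,0.96,0.04
48,negative_control,0,3000,930,31.00,0.16,1.03,0.06,,0.03,0.00
48,combined,21.5,3000,428,14.27,0.15,6.93,0.14,34.20,0.49,0.01
48,combined,43,3000,408,13.60,0.49,8.30,0.37,18.96,0.61,0.02
48,combined,64.5,3000,378,12.60,0.43,8.50,0.26,16.73,0.68,0.02
48,positive_control,4,3000,304,10.13,0.13,10.00,0.33,,1.03,0.01
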