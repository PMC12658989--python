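exposure_h,concentration_mg_ml,tcc,tcd,mi_percent,mi_sd,ca_percent,ca_sd,mf,mf_sd
24,0,3000,628,20.93,0.16,0.20,0.10,0.01,0.00
24,21.5,3000,520,17.33,0.09,3.67,0.32,0.21,0.00
24,43,3000,501,16.70,0.05,4.53,0.32,0.27,0.00
24,64.5,3000,485,16.16,0.45,5.13,0.29,0.32,0.01
48,0,3000,756,25.20,0.31,0.53,0.15,0.02,0.00
48,21.5,3000,476,15.87,0.23,4.27,0.40,0.27,0.00
48,43,3000,443,14.77,0.20,5.57,0.23,0.38,0.01
48,64.5,3000,387,12.90,0.38,6.17,0.53,0.48,0.01
72,0,3000,930,31.00,0.16,1.03,0.06,0.03,0.00
72,21.5,3000,423,14.10,0.33,4.77,0.23,0.34,0.01
72,43,3000,398,13.26,0.46,5.97,0.13,0.45,0.02
72,64.5,3000,376,12.53,0.33,7.17,0.25,0.57,0.02
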