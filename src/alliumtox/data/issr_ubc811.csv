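locus,weight_bp,neg_control,single_21.5,single_43,single_64.5,pos_control,combined_21.5,combined_43,combined_64.5,band_type_printed
1,1272.30,0,0,0,0,1,0,0,0,U
2,1078.16,0,0,0,0,1,0,0,0,U
3,955.85,1,1,0,1,0,0,1,0,P
4,884.98,0,0,0,0,1,0,0,0,P
5,742.80,1,1,1,1,1,1,1,1,M
6,642.55,0,1,1,1,1,1,1,1,P
7,528.85,1,1,1,1,1,1,1,1,M
8,447.21,0,0,0,0,1,0,0,0,P
9,412.96,1,1,1,0,0,1,0,0,P
10,343.49,0,0,0,0,0,0,1,0,P
11,300.00,1,1,1,1,0,1,1,1,P
12,213.22,1,0,0,1,0,0,0,0,P
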