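locus,weight_bp,neg_control,single_21.5,single_43,single_64.5,pos_control,combined_21.5,combined_43,combined_64.5,band_type_printed
1,3076.61,0,0,0,0,1,0,0,0,U
2,2022.75,0,0,0,0,1,0,0,0,U
3,1641.78,0,0,0,1,0,0,1,1,P
4,1377.18,0,0,0,0,1,0,0,0,U
5,1078.16,1,1,1,1,0,0,0,1,P
6,941.57,1,1,1,0,1,0,0,0,P
7,842.07,0,0,0,0,0,1,1,1,P
8,694.40,0,0,0,0,1,0,0,0,U
9,664.94,1,1,0,0,0,1,1,0,P
10,616.10,0,0,0,0,1,0,0,1,P
11,551.66,0,1,1,1,0,0,0,0,P
12,386.69,1,1,1,1,0,1,1,1,P
13,321.01,1,0,0,1,0,0,0,0,P
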