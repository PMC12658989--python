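locus,weight_bp,neg_control,single_21.5,single_43,single_64.5,pos_control,combined_21.5,combined_43,combined_64.5,band_type_printed
1,1445.94,0,0,0,0,1,0,0,0,U
2,1171.21,1,0,0,1,0,0,0,0,P
3,924.02,1,1,0,0,0,0,0,0,P
4,815.86,0,1,1,1,1,0,0,0,P
5,684.75,1,1,1,1,1,1,1,1,M
6,640.98,0,0,0,0,1,0,0,0,U
7,554.90,1,0,1,1,0,1,0,0,P
8,457.31,1,1,1,1,1,1,1,1,M
9,363.42,0,0,0,0,1,1,1,0,P
10,346.41,1,1,0,0,0,0,0,1,P
11,314.73,0,0,1,0,1,0,0,1,P
12,253.37,1,1,1,1,0,1,1,0,P
13,193.36,0,0,0,0,1,0,0,0,U
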