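locus,weight_bp,neg_control,single_21.5,single_43,single_64.5,pos_control,combined_21.5,combined_43,combined_64.5,band_type_printed
1,1389.93,1,1,1,1,0,1,0,1,P
2,1202.47,0,1,1,0,0,1,0,0,P
3,889.46,1,1,1,1,1,1,1,1,M
4,659.70,1,1,1,1,0,1,0,1,P
5,586.48,0,0,0,0,0,0,1,1,P
6,517.39,1,1,1,1,1,1,1,1,M
7,487.05,0,0,1,0,1,0,0,0,P
8,410.64,1,1,1,1,1,1,1,0,P
9,361.69,0,0,0,1,1,0,0,0,P
10,322.37,1,1,1,0,0,0,1,0,P
11,221.34,1,1,0,0,0,0,1,0,P
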