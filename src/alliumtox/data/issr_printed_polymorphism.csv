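primer,sample,percent
HB12,single_21.5,12.5
HB12,single_43,33.33
HB12,single_64.5,37.5
HB12,pos_control,66.66
HB12,combined_21.5,37.5
HB12,combined_43,37.5
HB12,combined_64.5,50
HB12,total,81.81
418,single_21.5,33.33
418,single_43,50
418,single_64.5,57.14
418,pos_control,90
418,combined_21.5,66.66
418,combined_43,71.43
418,combined_64.5,75
418,total,100
UBC-811,single_21.5,28.57
UBC-811,single_43,42.86
UBC-811,single_64.5,28.57
UBC-811,pos_control,81.81
UBC-811,combined_21.5,42.86
UBC-811,combined_43,50
UBC-811,combined_64.5,57.14
UBC-811,total,83.83
MAO,single_21.5,37.5
MAO,single_43,55.55
MAO,single_64.5,37.5
MAO,pos_control,84.62
MAO,combined_21.5,50
MAO,combined_43,62.5
MAO,combined_64.5,62.5
MAO,total,84.61
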