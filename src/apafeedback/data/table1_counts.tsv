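gene	ht_targeting	ht_total	nt_targeting	nt_total
CSTF1	28	203	61	601
CSTF2	76	203	172	601
CSTF3	23	203	63	601
CPSF1	7	203	6	601
CPSF2	79	203	158	601
CPSF3	6	203	9	601
CPSF4	28	203	62	601
NUDT21	81	203	201	601
CPSF6	136	203	365	601
CPSF7	138	203	380	601
FIP1L1	19	203	30	601
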