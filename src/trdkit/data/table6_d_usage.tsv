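subgroup	n_sequences	TRDD1_count	TRDD2_count	TRDD3_count	TRDD4_count	TRDD5_count	TRDD1_pct	TRDD2_pct	TRDD3_pct	TRDD4_pct	TRDD5_pct
TRDV1	73	33	33	18	23	29	24.3	24.3	13.2	16.9	21.3
TRDV2	17	6	9	7	9	6	16.2	24.3	18.9	24.3	16.2
TRDV3	17	9	3	10	4	5	29.0	9.7	32.2	12.9	16.1
TRDV4	36	9	16	11	16	9	14.8	26.2	18.0	26.2	14.8
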