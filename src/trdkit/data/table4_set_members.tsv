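set_id	members	cdr_imgt_lengths	n_genes
1	TRDV1a,TRDV1ac,TRDV1af,TRDV1b,TRDV1h,TRDV1k,TRDV1l,TRDV1m,TRDV1n,TRDV1s	[7.3.4]	10
2	TRDV1am,TRDV1an,TRDV1az,TRDV1t	[7.3.4][7.3.3][8.3.4]	4
3	TRDV1aa,TRDV1ah,TRDV1ax,TRDV1bm,TRDV1bn,TRDV1g,TRDV1r	[9.3.4]	7
4	TRDV1c,TRDV1aq	[9.3.4]	2
5	TRDV1aj,TRDV1ap,TRDV1ba,TRDV1bd,TRDV1d	[9.3.4]	5
6	TRDV1ag,TRDV1aw,TRDV1q,TRDV1bg,TRDV1bj	[9.3.4][9.3.15][9.3.12]	5
7	TRDV1bb,TRDV1bc,TRDV1ao	[10.3.4][5.3.4]	3
8	TRDV1ad,TRDV1p,TRDV1x	[9.3.4]	3
9	TRDV1ae,TRDV1ar,TRDV1f,TRDV1o	[7.0.4][18.0.4]	4
10	TRDV1i,TRDV1al,TRDV1u,TRDV1z	[7.3.4]	4
11	TRDV1w,TRDV1j,TRDV1bh,TRDV1v,TRDV1as	[7.3.4]	5
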