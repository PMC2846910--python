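set_id	cdr1_lengths	residue_57	w107	cdr2_deleted	exceptions
1	7	G	-	no
2	7	Y	+/-	no	TRDV1t:CDR1=8
3	9	E	+/-	no
4	9	Y	-	no
5	9	Y	+	no	TRDV1d:Q-at-107
6	9	Y|N	-	no
7	5|10	A|V	+	no
8	9	Y	+	no
9	7		+/-	yes	TRDV1o:CDR1=18
10	7	N|G	+	no
11	7	G|V	+	no
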