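locus_id	gene	phase	A	T	C	G	total	mutant_base	ref_base
SPEN_c2500	SPEN	pre	395	56	344112	71	344634	T	C
SPEN_c2500	SPEN	post	384	2228	366751	75	369440	T	C
HIP1_c2167	HIP1	pre	273	67	514588	138	515067	T	C
HIP1_c2167	HIP1	post	193	9007	413019	95	422316	T	C
TP53_c747	TP53	pre	1231	36	278734	162	280167	G	C
TP53_c747	TP53	post	2517	39	263754	601	266912	G	C
NSD1_c3049	NSD1	pre	27761	55	0	7	27823	G	A
NSD1_c3049	NSD1	post	23025	52	0	151	23228	G	A
WDFY3_c718	WDFY3	pre	15	64070	8	3	64096	C	T
WDFY3_c718	WDFY3	post	13	39801	169	2	39987	C	T
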