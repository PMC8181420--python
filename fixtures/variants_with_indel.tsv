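sample_id	chrom	pos	ref	alt	aaf	depth	pop_maf	region_class	consequence	gene
S01	chr1	1000	C	T	0.12	140		exonic	missense	GENE001
S01	chr1	2000	CA	C	0.21	95		exonic	other	GENE002
S02	chr1	1000	C	T	0.30	88	0.002	exonic	missense	GENE001
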