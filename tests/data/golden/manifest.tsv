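probe_id	chrom	pos	stratum	in_450k	in_850k	flag_sex	flag_snp	flag_crossreactive	flag_nonunique
cg00000001	chr1	100	II	1	1	0	0	0	0
cg00000002	chr2	250	I-red	1	0	0	1	0	0
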