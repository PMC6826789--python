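rsid	chrom	pos	locus	is_lead
rs882380	chr17	46300000	17q21.32	1
rs937213	chr15	40400000	15q15.1	1
rs7579014	chr2	60600000	2p16.1	1
rs11651052	chr17	36100000	17q12	1
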