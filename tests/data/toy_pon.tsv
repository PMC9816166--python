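chrom	pos	ref	alt
1	900	C	A
1	1000	C	G
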