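##fileformat=VCFv4.2
##INFO=<ID=TNC,Number=1,Type=String,Description="Pyrimidine-centred trinucleotide context">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=1>
##contig=<ID=2>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	TUMOR	NORMAL
1	100	.	C	T	.	PASS	TNC=ACG	AD:DP	30,20:50	50,0:50
1	200	.	C	T	.	PASS	TNC=ACA	AD:DP	5,4:9	50,0:50
1	300	.	C	A	.	PASS	TNC=GCA	AD:DP	30,20:50	9,0:9
1	400	.	T	C	.	PASS	TNC=ATA	AD:DP	30,20:50	48,2:50
1	500	.	T	G	.	PASS	TNC=CTC	AD:DP	25,25:50	49,1:50
1	600	.	C	G	.	PASS	TNC=ACT	AD:DP	30,20:50	50,0:50
1	700	.	C	T	.	PASS	TNC=TCG	AD:DP	30,20:50	50,0:50
1	800	.	T	A	.	PASS	TNC=GTG	AD:DP	30,20:50	50,0:50
1	900	.	C	A	.	PASS	TNC=CCA	AD:DP	30,20:50	50,0:50
1	1000	.	C	T	.	PASS	TNC=GCG	AD:DP	30,20:50	50,0:50
2	150	.	C	T	.	PASS	TNC=ACG	AD:DP	30,20:50	50,0:50
2	250	.	T	C	.	PASS	TNC=TTA	AD:DP	30,20:50	50,0:50
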