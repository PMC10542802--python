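##fileformat=VCFv4.2
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FILTER=<ID=strand_bias,Description="strand bias">
##FILTER=<ID=germline,Description="likely germline">
##contig=<ID=chrM,length=16569>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	SAMPLE1
chrM	100	.	T	C	.	PASS	.	AF:DP	0.1200:850
chrM	1500	.	G	A	.	PASS	.	AF:DP	0.0700:920
chrM	3308	.	T	G	.	PASS	.	AF:DP	0.2500:1010
chrM	5000	.	T	C	.	PASS	.	AF:DP	0.5000:1100
chrM	7000	.	A	G	.	PASS	.	AF:DP	0.9600:990
chrM	9500	.	A	G	.	PASS	.	AF:DP	0.0400:870
chrM	12000	.	C	CAT	.	PASS	.	AF:DP	0.3000:900
chrM	12500	.	CA	C	.	PASS	.	AF:DP	0.2000:950
chrM	16100	.	T	C	.	PASS	.	AF:DP	0.1500:289
chrM	14000	.	T	C	.	strand_bias	.	AF:DP	0.1000:800
chrM	366	.	G	A	.	PASS	.	AF:DP	0.0800:700
chrM	6000	.	G	A	.	germline	.	AF:DP	0.1100:780
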