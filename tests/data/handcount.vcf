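##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count across genotypes">
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	A	B	C	D
1	100	.	A	G	.	PASS	AC=1;AA=A	GT	0/1	0/0	0/0	0/0
1	200	.	C	T	.	PASS	AC=1;AA=.	GT	0/0	0/1	0/0	0/0
1	300	.	G	A	.	PASS	AC=1;AA=-	GT	0/0	0/0	0/1	0/0
1	400	.	T	C	.	PASS	AC=1;AA=N	GT	0/0	0/0	0/0	0/1
1	500	.	A	C	.	PASS	AC=1;AA=C	GT	0/1	0/0	0/0	0/0
1	600	.	G	T	.	PASS	AC=2;AA=G	GT	0/0	1/1	0/0	0/0
1	700	.	C	G	.	PASS	AC=2;AA=C	GT	0/1	0/0	0/1	0/0
1	800	.	T	A	.	PASS	AC=3;AA=T	GT	0/0	1/1	0/0	0/1
1	900	.	A	T	.	PASS	AC=2;AA=A	GT	0/1	0/1	0/0	0/0
1	1000	.	G	C	.	PASS	AC=3;AA=G	GT	0/0	0/0	1/1	0/1
1	1100	.	AT	A	.	PASS	AC=1;AA=A	GT	0/0	0/1	0/0	0/0
1	1200	.	A	G,T	.	PASS	AC=1,1;AA=A	GT	0/1	0/0	0/2	0/0
1	1300	.	C	A	.	PASS	AC=0;AA=C	GT	0/0	0/0	0/0	0/0
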