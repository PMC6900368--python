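Chromosome	Position	Build	ID	Gene	Mutation	Consequence	Depth	Ref	Alt	Clinvar	GnomAD	TOPMED	ExAC	SIFT	Polyphen2 HDIV	Polyphen2 HVAR	LRT	Mutation Taster	Mutation Assessor	PROVEAN	FATHMM	GERP_RS	MetaSVM score	MetaSVM pred
2	21259976	hg19	-	APOB	exon6: c.G689T: p.G230V	missense	50	G	T	-	-	-	-	D	D	D	D	D	M	D	T	5.64	-0.4609	T
4	673778	hg19	rs2228354	MYL5	exon4: c.T263C: p.F88S	missense	50	T	C	Not reported	0.00665	0.00593	0.0069	D	D	D	U	D	H	D	D	4.12	0.7855	D
8	16001102	hg19	-	MSR1	exon8: c.G998T: p.G333V	missense	50	G	T	-	-	-	-	D	D	D	D	D	H	D	D	4.9	1.0032	D
9	107589238	hg19	rs138880920	ABCA1	exon16: c.G2328C: p.K776N	missense	50	G	C	Likely benign	0.0033	0.00198	0.0036	D	D	D	D	D	M	D	D	3.27	0.3243	D
11	18637499	hg19	rs66514853	SPTY2D1	exon3: c.320_322del AGA: p.K107del	nonframeshift_indel	50	AGA	-	Not reported	0.01726	0.01695	0.0169	-	-	-	-	-	-	-	-	-	-	-
16	67976320	hg19	rs4986970	LCAT	exon5: c.T694A: p.S232T	missense	50	T	A	-	0.01758	0.01669	0.01807	T	D	P	U	D	L	N	D	3.84	0.1186	D
17	53844742	hg19	rs112454522	PCTP	exon2: c.G188A: p.C63Y	missense	50	G	A	-	0.00473	0.00444	0.0049	D	D	D	D	D	M	D	T	5.64	-0.6575	T
19	11227604	hg19	rs137929307	LDLR	exon12: c.G1775A: p.G592E	missense	50	G	A	Pathogenic/Likely pathogenic	0.00004	0.00003	0.00005	D	D	D	D	D	M	D	D	5.48	1.0446	D
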