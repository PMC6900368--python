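Chromosome	Position	Build	ID	Gene	Mutation	Consequence	Depth	Ref	Alt	Clinvar	GnomAD	TOPMED	ExAC	SIFT	Polyphen2 HDIV	Polyphen2 HVAR	LRT	Mutation Taster	Mutation Assessor	PROVEAN	FATHMM	GERP_RS	MetaSVM score	MetaSVM pred
2	11919668	hg19	rs141555457	LPIN1	exon6: c.C746A: p.T249K	missense	50	C	A	Not reported	0.00054	0.00017	0.00048	D	D	P	D	D	M	D	D	4.85	0.5039	D
3	52556168	hg19	rs566837633	STAB1	exon59: c.C6387G: p.S2129R	missense	50	C	G	Not reported	0.00092	0.00035	0.00081	D	D	P	N	D	L	D	D	3.83	0.4546	D
8	16012594	hg19	rs41341748	MSR1	exon6: c.C877T: p.R293X	stopgain	50	C	T	Pathogenic; uncertain significance. Hereditary cancer	0.00821	0.00765	0.0077	-	-	-	-	-	-	-	-	2.84	-	-
10	101594176	hg19	rs142715085	ABCC2	exon24: c.C3298A: p.R1100S	missense	50	C	A	Uncertain significance	0.00048	0.0007	0.0005	T	D	D	D	D	L	D	D	4.38	0.5245	D
17	76395566	hg19	rs780258683	PGS1	exon5: c.G649A: p.G217S	missense	50	G	A	Not reported	0.00002	0.00002	0.00002	D	D	D	D	D	M	T	T	5.5	-0.5799	T
18	21957382	hg19	rs766116535	OSBPL1A	exon2: c.114_115insAATT: p.C39fs	frameshift	50	-	AATT	Not reported	0.0022	0.00259	0.00187	-	-	-	-	-	-	-	-	-	-	-
18	58038777	hg19	rs79783591	MC4R	exon1: c.T806A: p.I269N	missense	50	T	A	Likely pathogenic; uncertain significance: Obesity	0.00103	0.00026	0.00081	D	D	D	D	D	L	D	T	5.85	-0.7544	T
19	11215918	hg19	rs752191968	LDLR	exon4: c.337dupG: p.E113fs	frameshift	50	-	G	Pathogenic: Familial hypercholesterolemia	-	-	0.00001	-	-	-	-	-	-	-	-	-	-	-
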