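variant_id	gene	ref	alt	1-1	1-2	1-3	2-1	2-2
LPIN1:p.T249K	LPIN1	C	A	CA	CA	CA	CC	CA
STAB1:p.S2129R	STAB1	C	G	CG	CG	CC	CC	CG
MSR1:p.R293X	MSR1	C	T	CT	CT	CT	CT	CC
ABCC2:p.R1100S	ABCC2	C	A	CA	CC	CA	CC	CA
PGS1:p.G217S	PGS1	G	A	GA	GG	GA	GA	GG
OSBPL1A:p.C39fs	OSBPL1A	-	AATT	-/AATT	-/-	-/-	-/AATT	-/-
MC4R:p.I269N	MC4R	T	A	TA	TT	TT	TT	TA
LDLR:p.E113fs	LDLR	-	G	G/G	-/G	G/G	-/G	-/G
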