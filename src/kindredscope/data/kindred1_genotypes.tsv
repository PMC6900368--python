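variant_id	gene	ref	alt	1-1	1-2	1-3	1-4	1-6	2-1	2-2	2-3	2-5	3-1	3-2	3-3
APOB:p.G230V	APOB	G	T	GT	GT	GG	GG	GG	GG	GG	GT	GG	GG	GG	GT
MYL5:p.F88S	MYL5	T	C	TC	TT	TT	TT	TT	TT	TT	TC	TT	TT	TT	TT
MSR1:p.G333V	MSR1	G	T	GT	GG	GG	GG	GG	GG	GT	GG	GG	GG	GT	GG
ABCA1:p.K776N	ABCA1	G	C	GC	GG	GG	GG	GG	GG	GG	GC	GG	GG	GG	GC
SPTY2D1:p.K107del	SPTY2D1	AGA	-	AGA/-	AGA/-	AGA/-	AGA/AGA	AGA/AGA	AGA/-	AGA/-	AGA/AGA	AGA/AGA	AGA/-	AGA/AGA	AGA/AGA
LCAT:p.S232T	LCAT	T	A	TA	TA	TA	TT	TT	TT	TT	TA	TT	TT	TT	TT
PCTP:p.C63Y	PCTP	G	A	GA	GA	GG	GG	GG	GG	GG	GA	GG	GG	GG	GG
LDLR:exon1del	LDLR	-	del	-/del	-/del	-/del	-/-	-/-	-/-	-/-	-/del	-/-	-/-	-/-	-/del
LDLR:p.G592E	LDLR	G	A	GA	GG	GG	GG	GG	GA	GA	GG	GG	GG	GA	GG
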