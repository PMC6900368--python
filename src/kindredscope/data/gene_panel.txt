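# Candidate lipid-metabolism genes (abbreviated panel bundled for the worked
# examples; supply your own curated list for real analyses).
LDLR
APOB
PCSK9
LDLRAP1
STAP1
CYP7A1
LIPA
ABCG5
ABCG8
MYL5
MSR1
ABCA1
SPTY2D1
LCAT
PCTP
LPIN1
STAB1
ABCC2
PGS1
OSBPL1A
MC4R
APOE
APOC3
CETP
LPL
LIPC
SCARB1
ANGPTL3
NPC1L1
SORT1
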