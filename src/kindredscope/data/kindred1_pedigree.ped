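#FID	IID	FAT	MOT	SEX	PHENO	AGE	BMI	TC	HDL	TG	LDL
K1	1-1	2-3	2-2	2	0	-	-	-	36	-	719
K1	1-2	2-3	2-2	2	0	-	-	-	42	-	315
K1	1-3	2-3	2-2	1	0	-	-	-	55	-	232
K1	1-4	2-5	2-1	0	0	-	-	-	56	-	102
K1	1-6	2-5	2-1	0	0	-	-	-	85	-	171
K1	2-1	3-2	3-1	2	0	-	-	-	68	-	221
K1	2-2	3-2	3-1	2	0	-	-	-	62	-	192
K1	2-3	0	3-3	1	0	-	-	-	46	-	301
K1	2-5	0	0	0	0	-	-	-	32	-	130
K1	3-1	0	0	2	0	-	-	-	50	-	146
K1	3-2	0	0	1	0	-	-	-	81	-	393
K1	3-3	0	0	2	0	-	-	-	48	-	383
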