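#FID	IID	FAT	MOT	SEX	PHENO	AGE	BMI	TC	HDL	TG	LDL
K2	1-1	2-1	2-2	2	0	-	-	-	20	-	672
K2	1-2	2-1	2-2	2	0	-	-	-	23	-	205
K2	1-3	2-1	2-2	2	0	-	-	-	25	-	791
K2	2-1	0	0	1	0	-	-	-	56	-	266
K2	2-2	0	0	2	0	-	-	-	30	-	243
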