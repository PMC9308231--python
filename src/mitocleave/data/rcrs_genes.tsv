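name	biotype	start	end	strand
MT-TF	tRNA	577	647	+
MT-RNR1	rRNA	648	1601	+
MT-TV	tRNA	1602	1670	+
MT-RNR2	rRNA	1671	3229	+
MT-TL1	tRNA	3230	3304	+
MT-ND1	mRNA	3307	4262	+
MT-TI	tRNA	4263	4331	+
MT-TQ	tRNA	4329	4400	-
MT-TM	tRNA	4402	4469	+
MT-ND2	mRNA	4470	5511	+
MT-TW	tRNA	5512	5579	+
MT-TA	tRNA	5587	5655	-
MT-TN	tRNA	5657	5729	-
MT-TC	tRNA	5761	5826	-
MT-TY	tRNA	5826	5891	-
MT-CO1	mRNA	5904	7445	+
MT-TS1	tRNA	7446	7514	-
MT-TD	tRNA	7518	7585	+
MT-CO2	mRNA	7586	8269	+
MT-TK	tRNA	8295	8364	+
MT-ATP8	mRNA	8366	8572	+
MT-ATP6	mRNA	8527	9207	+
MT-CO3	mRNA	9207	9990	+
MT-TG	tRNA	9991	10058	+
MT-ND3	mRNA	10059	10404	+
MT-TR	tRNA	10405	10469	+
MT-ND4L	mRNA	10470	10766	+
MT-ND4	mRNA	10760	12137	+
MT-TH	tRNA	12138	12206	+
MT-TS2	tRNA	12207	12265	+
MT-TL2	tRNA	12266	12336	+
MT-ND5	mRNA	12337	14148	+
MT-ND6	mRNA	14149	14673	-
MT-TE	tRNA	14674	14742	-
MT-CYB	mRNA	14747	15887	+
MT-TT	tRNA	15888	15953	+
MT-TP	tRNA	15956	16023	-
D-loop	control_region	16024	16569	+
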