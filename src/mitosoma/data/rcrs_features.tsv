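gene	start	end	strand	kind	complex
D-loop	16024	16569	heavy	dloop	none
D-loop	1	576	heavy	dloop	none
MT-TF	577	647	heavy	tRNA	none
MT-RNR1	648	1601	heavy	rRNA	none
MT-TV	1602	1670	heavy	tRNA	none
MT-RNR2	1671	3229	heavy	rRNA	none
MT-TL1	3230	3304	heavy	tRNA	none
MT-ND1	3307	4262	heavy	protein	Complex I
MT-TI	4263	4331	heavy	tRNA	none
MT-TQ	4329	4400	light	tRNA	none
MT-TM	4402	4469	heavy	tRNA	none
MT-ND2	4470	5511	heavy	protein	Complex I
MT-TW	5512	5579	heavy	tRNA	none
MT-TA	5587	5655	light	tRNA	none
MT-TN	5657	5729	light	tRNA	none
MT-TC	5761	5826	light	tRNA	none
MT-TY	5826	5891	light	tRNA	none
MT-CO1	5904	7445	heavy	protein	Complex IV
MT-TS1	7446	7514	light	tRNA	none
MT-TD	7518	7585	heavy	tRNA	none
MT-CO2	7586	8269	heavy	protein	Complex IV
MT-TK	8295	8364	heavy	tRNA	none
MT-ATP8	8366	8572	heavy	protein	ATP synthase
MT-ATP6	8527	9207	heavy	protein	ATP synthase
MT-CO3	9207	9990	heavy	protein	Complex IV
MT-TG	9991	10058	heavy	tRNA	none
MT-ND3	10059	10404	heavy	protein	Complex I
MT-TR	10405	10469	heavy	tRNA	none
MT-ND4L	10470	10766	heavy	protein	Complex I
MT-ND4	10760	12137	heavy	protein	Complex I
MT-TH	12138	12206	heavy	tRNA	none
MT-TS2	12207	12265	heavy	tRNA	none
MT-TL2	12266	12336	heavy	tRNA	none
MT-ND5	12337	14148	heavy	protein	Complex I
MT-ND6	14149	14673	light	protein	Complex I
MT-TE	14674	14742	light	tRNA	none
MT-CYB	14747	15887	heavy	protein	Complex III
MT-TT	15888	15953	heavy	tRNA	none
MT-TP	15956	16023	light	tRNA	none
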