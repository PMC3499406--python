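# Gene annotation of the human mitochondrial genome (rCRS, NC_012920.1),
# transcribed from the NCBI feature table. Coordinates are 1-based inclusive
# on the heavy strand; incomplete_stop_len is the number of terminal stop-codon
# bases present in the genome (the stop is completed by mRNA polyadenylation).
# version: 1
symbol	gene_type	start	end	strand	incomplete_stop_len
MT-TF	tRNA	577	647	H	0
MT-RNR1	rRNA	648	1601	H	0
MT-TV	tRNA	1602	1670	H	0
MT-RNR2	rRNA	1671	3229	H	0
MT-TL1	tRNA	3230	3304	H	0
MT-ND1	protein	3307	4262	H	2
MT-TI	tRNA	4263	4331	H	0
MT-TQ	tRNA	4329	4400	L	0
MT-TM	tRNA	4402	4469	H	0
MT-ND2	protein	4470	5511	H	1
MT-TW	tRNA	5512	5579	H	0
MT-TA	tRNA	5587	5655	L	0
MT-TN	tRNA	5657	5729	L	0
MT-TC	tRNA	5761	5826	L	0
MT-TY	tRNA	5826	5891	L	0
MT-CO1	protein	5904	7445	H	0
MT-TS1	tRNA	7446	7514	L	0
MT-TD	tRNA	7518	7585	H	0
MT-CO2	protein	7586	8269	H	0
MT-TK	tRNA	8295	8364	H	0
MT-ATP8	protein	8366	8572	H	0
MT-ATP6	protein	8527	9207	H	0
MT-CO3	protein	9207	9990	H	1
MT-TG	tRNA	9991	10058	H	0
MT-ND3	protein	10059	10404	H	1
MT-TR	tRNA	10405	10469	H	0
MT-ND4L	protein	10470	10766	H	0
MT-ND4	protein	10760	12137	H	1
MT-TH	tRNA	12138	12206	H	0
MT-TS2	tRNA	12207	12265	H	0
MT-TL2	tRNA	12266	12336	H	0
MT-ND5	protein	12337	14148	H	0
MT-ND6	protein	14149	14673	L	0
MT-TE	tRNA	14674	14742	L	0
MT-CYB	protein	14747	15887	H	1
MT-TT	tRNA	15888	15953	H	0
MT-TP	tRNA	15956	16023	L	0
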