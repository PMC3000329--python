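# Gene annotation of the human mitochondrial reference (rCRS numbering, 1-based inclusive).
# Columns: name	start	end	strand	kind
# strand: H = heavy (plus), L = light (coding sequence is the reverse complement)
name	start	end	strand	kind
tRNA-Phe	577	647	H	tRNA
RNR1	648	1601	H	rRNA
tRNA-Val	1602	1670	H	tRNA
RNR2	1671	3229	H	rRNA
tRNA-Leu1	3230	3304	H	tRNA
ND1	3307	4262	H	protein
tRNA-Ile	4263	4331	H	tRNA
tRNA-Gln	4329	4400	L	tRNA
tRNA-Met	4402	4469	H	tRNA
ND2	4470	5511	H	protein
tRNA-Trp	5512	5579	H	tRNA
tRNA-Ala	5587	5655	L	tRNA
tRNA-Asn	5657	5729	L	tRNA
tRNA-Cys	5761	5826	L	tRNA
tRNA-Tyr	5826	5891	L	tRNA
COX1	5904	7445	H	protein
tRNA-Ser1	7446	7514	L	tRNA
tRNA-Asp	7518	7585	H	tRNA
COX2	7586	8269	H	protein
tRNA-Lys	8295	8364	H	tRNA
ATP8	8366	8572	H	protein
ATP6	8527	9207	H	protein
COX3	9207	9990	H	protein
tRNA-Gly	9991	10058	H	tRNA
ND3	10059	10404	H	protein
tRNA-Arg	10405	10469	H	tRNA
ND4L	10470	10766	H	protein
ND4	10760	12137	H	protein
tRNA-His	12138	12206	H	tRNA
tRNA-Ser2	12207	12265	H	tRNA
tRNA-Leu2	12266	12336	H	tRNA
ND5	12337	14148	H	protein
ND6	14149	14673	L	protein
tRNA-Glu	14674	14742	L	tRNA
CYTB	14747	15887	H	protein
tRNA-Thr	15888	15953	H	tRNA
tRNA-Pro	15956	16023	L	tRNA
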