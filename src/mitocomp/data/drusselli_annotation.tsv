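locus	strand	start	end	category	anticodon	start_codon	stop_codon	a_pct	t_pct	g_pct	c_pct
tRNA-Phe	H	1	68	tRNA	GAA	.	.	35.3	19.1	23.5	22.1
12S-rRNA	H	69	1022	rRNA	.	.	.	30.8	21.4	22.0	25.8
tRNA-Val	H	1023	1094	tRNA	TAC	.	.	30.6	19.4	23.6	26.4
16S-rRNA	H	1095	2817	rRNA	.	.	.	32.4	22.0	20.1	25.4
tRNA-Leu(TAA)	H	2818	2891	tRNA	TAA	.	.	28.4	23.0	23.0	25.7
ND1	H	2892	3866	PCG	.	ATG	TAA	23.4	26.4	16.0	34.3
tRNA-Ile	H	3872	3941	tRNA	GAT	.	.	27.1	21.4	28.6	22.9
tRNA-Gln	L	3941	4011	tRNA	TTG	.	.	35.2	25.4	15.5	23.9
tRNA-Met	H	4011	4080	tRNA	CAT	.	.	25.7	25.7	22.9	25.7
ND2	H	4081	5125	PCG	.	ATG	T--	27.2	24.1	12.2	36.5
tRNA-Trp	H	5126	5196	tRNA	TCA	.	.	32.4	16.9	25.4	25.4
tRNA-Ala	L	5198	5266	tRNA	TGC	.	.	34.8	24.6	14.5	26.1
tRNA-Asn	L	5268	5340	tRNA	GTT	.	.	32.9	20.5	17.8	28.8
tRNA-Cys	L	5379	5445	tRNA	GCA	.	.	26.9	26.9	22.4	23.9
tRNA-Tyr	L	5446	5515	tRNA	GTA	.	.	30.0	22.9	18.6	28.6
COI	H	5517	7067	PCG	.	GTG	TAA	24.5	29.7	18.6	27.2
tRNA-Ser(TGA)	L	7068	7138	tRNA	TGA	.	.	28.2	23.9	19.7	28.2
tRNA-Asp	H	7142	7212	tRNA	GTC	.	.	29.6	28.2	21.1	21.2
COII	H	7220	7910	PCG	.	ATG	T--	27.9	25.3	16.6	30.1
tRNA-Lys	H	7911	7984	tRNA	TTT	.	.	31.1	21.6	20.3	27.0
ATP8	H	7986	8150	PCG	.	ATG	TAG	24.1	26.8	13.9	35.2
ATP6	H	8144	8827	PCG	.	ATG	TAA	24.1	26.8	13.9	35.2
COIII	H	8827	9611	PCG	.	ATG	TA-	23.9	26.6	17.8	31.6
tRNA-Gly	H	9612	9681	tRNA	TCC	.	.	37.1	28.6	15.7	18.6
ND3	H	9682	10030	PCG	.	ATG	T--	22.1	29.2	15.5	33.2
tRNA-Arg	H	10031	10099	tRNA	TCG	.	.	31.9	33.3	18.8	15.9
ND4L	H	10101	10397	PCG	.	ATG	TAA	22.2	27.9	15.5	34.3
ND4	H	10391	11771	PCG	.	ATG	T--	25.6	25.8	14.7	34.0
tRNA-His	H	11772	11843	tRNA	GTG	.	.	29.2	29.2	19.4	22.2
tRNA-Ser(GCT)	H	11844	11911	tRNA	GCT	.	.	25.0	17.6	25.0	32.4
tRNA-Leu(TAG)	H	11917	11989	tRNA	TAG	.	.	31.5	23.3	20.5	24.7
ND5	H	11990	13828	PCG	.	ATG	TAG	26.6	26.4	14.2	32.7
ND6	L	13825	14346	PCG	.	ATG	TAG	13.8	36.0	33.3	16.9
tRNA-Glu	L	14347	14415	tRNA	TCC	.	.	33.3	21.7	17.4	27.5
Cytb	H	14420	15560	PCG	.	ATG	T--	23.7	27.1	15.8	33.5
tRNA-Thr	H	15561	15632	tRNA	TGT	.	.	22.2	23.6	26.4	27.8
tRNA-Pro	L	15632	15702	tRNA	TGG	.	.	33.8	25.4	12.7	28.2
D-loop	H	15703	16542	control_region	.	.	.	33.0	30.6	16.3	20.1
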