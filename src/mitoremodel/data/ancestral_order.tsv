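# Ancestral arthropod-like mitochondrial gene arrangement (37 genes: 13 PCGs,
# 2 rRNAs, 22 tRNAs), anchored to start at COX1 on the plus strand. This is
# the conserved ground-pattern arrangement retained by the horseshoe crab,
# conventionally used as the outgroup/ancestral reference for panarthropod
# gene-order comparisons. Lengths are typical gene lengths in bases, used by
# the synthetic-genome generator as sampling templates.
position	label	cls	sign	length
1	COX1	PCG	1	1536
2	COX2	PCG	1	684
3	trnK	tRNA	1	64
4	trnD	tRNA	1	62
5	ATP8	PCG	1	159
6	ATP6	PCG	1	672
7	COX3	PCG	1	786
8	trnG	tRNA	1	59
9	ND3	PCG	1	351
10	trnA	tRNA	1	61
11	trnR	tRNA	1	58
12	trnN	tRNA	1	63
13	trnS1	tRNA	1	56
14	trnE	tRNA	1	60
15	trnF	tRNA	-1	61
16	ND5	PCG	-1	1716
17	trnH	tRNA	-1	59
18	ND4	PCG	-1	1338
19	ND4L	PCG	-1	294
20	trnT	tRNA	1	62
21	trnP	tRNA	-1	60
22	ND6	PCG	1	519
23	CYTB	PCG	1	1134
24	trnS2	tRNA	1	65
25	ND1	PCG	-1	939
26	trnL1	tRNA	-1	60
27	trnL2	tRNA	-1	63
28	rrnL	rRNA	-1	1230
29	trnV	tRNA	-1	60
30	rrnS	rRNA	-1	745
31	trnI	tRNA	1	62
32	trnQ	tRNA	-1	64
33	trnM	tRNA	1	61
34	ND2	PCG	1	1020
35	trnW	tRNA	1	60
36	trnC	tRNA	-1	57
37	trnY	tRNA	-1	61
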