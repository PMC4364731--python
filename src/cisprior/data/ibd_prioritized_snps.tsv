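chrom	pos	rsid	r2	lead_rsid	cadd	gwava	regdb	genes
1	22706434	rs6684375	1	rs12568930	13.02	0.44	2b	-
2	198905874	rs892513	0.97	rs1016883	14.41	0.4	1f	PLCL1
5	55438580	rs6859219	0.99	rs10065637	14.68	0.41	2b	ANKRD55
6	90856878	rs1010473	0.89	rs1847472	15.44	0.58	2b	BACH2
6	138002175	rs6927172	1	rs6920220	13.8	0.58	2b	-
8	130604563	rs13277237	0.89	rs1991866	12.78	0.58	2b	CCDC26
10	35426755	rs17499247	0.87	rs11010067	13.8	0.47	1f	CREM,RNU7-77P
11	61564299	rs4246215	1	rs4246215	10.67	0.78	1f	FADS1,FADS2,FEN1,MIR611
11	65656564	rs2231884	1	rs2231884	10.92	0.57	1b	CCDC85B,FIBP,FOSL1
15	67442596	rs17293632	1	rs17293632	13.47	0.46	2a	SMAD3
16	23853860	rs7200798	0.91	rs7404095	13.26	0.44	1f	PRKCB
17	37912377	rs12946510	1	rs12946510	11.41	0.5	1b	-
17	37970149	rs9909593	0.87	rs12946510	18.53	0.44	1f	IKZF3
20	31349908	rs6087990	0.82	rs4911259	13.54	0.68	2b	DNMT3B
20	31380309	rs1474738	0.99	rs4911259	13.11	0.42	2b	DNMT3B
20	44735854	rs6065926	0.99	rs1569723	16.82	0.65	1f	-
20	44746982	rs1883832	0.98	rs1569723	11.83	0.81	1f	CD40
22	21980638	rs5754426	0.85	rs2266959	10.1	0.42	2b	UBE2L3,YDJC
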