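disease	lead_rsid	proxy_rsid	r2
IBD	rs12568930	rs6684375	1
IBD	rs1016883	rs892513	0.97
IBD	rs10065637	rs6859219	0.99
RA	rs6859219	rs6859219	1
IBD	rs1847472	rs1010473	0.89
CeD	rs2327832	rs6927172	0.93
IBD	rs6920220	rs6927172	1
RA	rs6920220	rs6927172	1
IBD	rs1991866	rs13277237	0.89
IBD	rs11010067	rs17499247	0.87
IBD	rs4246215	rs4246215	1
IBD	rs2231884	rs2231884	1
IBD	rs17293632	rs17293632	1
IBD	rs7404095	rs7200798	0.91
IBD	rs12946510	rs12946510	1
IBD	rs12946510	rs9909593	0.87
IBD	rs4911259	rs6087990	0.82
IBD	rs4911259	rs1474738	0.99
IBD	rs1569723	rs6065926	0.99
RA	rs4810485	rs6065926	0.97
RA	rs4239702	rs6065926	0.85
IBD	rs1569723	rs1883832	0.98
RA	rs4810485	rs1883832	1
RA	rs4239702	rs1883832	0.88
AS	rs2283790	rs5754426	0.99
CeD	rs2298428	rs5754426	0.89
IBD	rs2266959	rs5754426	0.85
Ps	rs4821124	rs5754426	1
RA	rs11089637	rs5754426	0.83
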