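chromosome	start_bp	end_bp	gene	category
1	5000000	5400000	RSU1	ATO
2	12000000	12350000	TTC6	ATO
3	30000000	30500000	TSHR	ATO
4	45000000	45300000	ACSL1	ATO
1	20000000	20400000	TH	BM
2	33000000	33250000	COMT	BM
3	8000000	8450000	SEZ6L	BM
4	15000000	15300000	GTF2I	BM
5	27000000	27500000	GTF2IRD1	BM
6	40000000	40350000	TXNRD2	BM
1	36000000	36400000	MLPH	CC
2	48000000	48300000	MITF	CC
3	52000000	52450000	AP3B1	CC
4	4000000	4250000	PMEL	CC
5	10000000	10300000	CBD103	CC
6	18000000	18500000	KIT	CC
7	25000000	25350000	ASIP	CC
7	41000000	41400000	TYR	CC
8	7000000	7300000	TYRP1	CC
8	31000000	31450000	MC1R	CC
9	22000000	22300000	SLC45A2	CC
9	44000000	44350000	AGT	SE
10	6000000	6400000	ADRB2	SE
10	29000000	29250000	ADRB3	SE
1	50000000	50500000	HIF1A	SE
2	3000000	3300000	BDKRB2	SE
3	42000000	42400000	MSTN	SE
5	47000000	47350000	IL6	SE
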