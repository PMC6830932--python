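snp	chrom	pos	gene	model	case_counts	control_counts
rs885863	7	159028278	VIPR2	R	56/219/159	31/59/48
rs3113275	7	70514208	AUTS2	R	30/151/249	1/54/80
rs11764092	7	70732598	AUTS2	D	15/145/273	3/31/104
rs135763	22	38312399	CSNK1E	D	16/103/316	4/51/82
rs1534891	22	38299094	CSNK1E	D	12/96/327	5/45/88
rs80136044	2	238274081	PER2	D	7/101/327	1/17/120
rs3754729	2	238241585	PER2/HES6	D	41/202/189	12/47/78
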