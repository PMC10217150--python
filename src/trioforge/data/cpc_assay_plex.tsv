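rsid	position	gene	n_alleles	coverage_printed	nocall	total	common	het	rage
rs77650227	19:8888842	MUC16	2	100	0	37	13	4	4
rs10233232	7:48046564	C7orf57	2	100	0	37	11	9	9
rs358231	4:22818881	GBA3	2	100	0	37	15	7	7
rs55793208	5:179833099	SQSTM1	2	100	0	37	9	12	12
rs2947594	10:122697936	C10orf120	2	100	0	37	5	11	11
rs139094790	8:100709499	PABPC1	2	95	2	37	12	4	4
rs199887787	5:179837704	SQSTM1	2	100	0	37	12	4	4
rs2285738	7:25142293	C7orf31	2	100	0	37	9	12	12
rs1060271	5:179837132	SQSTM1	2	100	0	37	14	3	3
rs577355457	6:109528998	AK9	2	100	0	37	25	12	12
rs1612176	17:21416455	KCNJ12	2	100	0	37	15	5	5
rs6477845	9:111700042	SHOC1	2	100	0	37	12	12	12
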