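gene	chrom	pos	ref	alt	consequence	af_pop	cadd_phred	gerp	sift	polyphen	probands	acmg_printed	hgvs_g
FRG1	4	189957414	T	A	missense	1.9e-05	40	4.19	deleterious	damaging	Z19;Z99	PVS1,PM2,PP3	NC_000004.12:g.189957414T>A
TAF1B	2	9904885	C	T	stop_gained	0.0003156	1.31	5.67			Z15;Z19;Z34;Z42;Z46;Z54;Z62;Z66;Z74	PVS1,BS1	NC_000002.12:g.9904885C>T
MUC5B	11	1238987	C	T	missense	1.972e-05	1.07		deleterious	damaging	Z15;Z19;Z34;Z42;Z46;Z54;Z62;Z66;Z74;Z99;Z03;Z07;Z21;Z88;Z91		NC_000011.10:g.1238987C>T
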