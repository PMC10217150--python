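variant_class	proband_total	proband_mean_printed	control_total	control_mean_printed	combined_total	pct_probands_printed	pct_controls_printed
total	13450685	840667	35751971	777216.76	49202656
snp	12404198	775262	33893726	736820.13	46297924	25.2104236	68.88596827
indel	1046487	65405.4	2904835	63148.587	3951322	2.12689128	5.903817469
missense	172232	10764.5	483790	10517.174	656022	0.350046144	0.983259928
frameshift	10572	660.75	30183	656.15217	40755	0.021486645	0.061344249
stop_gain	2460	153.75	6778	147.34783	9238	0.00499973	0.013775679
stop_lost	469	29.3125	1280	27.826087	1749	0.000953201	0.002601486
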