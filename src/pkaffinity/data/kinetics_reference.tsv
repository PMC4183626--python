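system	peptide	vmax_umol_min_mg	km_uM	vmax_over_km	ddg_es_exp_kcal	ddg_ts_exp_kcal	is_reference
WT	LRRASLG	20.2	16.0	1.26250	0.00	0.00	1
R18A	LARASLG	8.7	4900.0	0.00178	3.39	3.89	0
R19A	LRAASLG	5.3	6300.0	0.00084	3.54	4.33	0
R18K	LKRASLG	17.1	1400.0	0.01221	2.65	2.75	0
R19K	LRKASLG	16.9	260.0	0.06500	1.65	1.76	0
R18H	LHRASLG	12.1	415.0	0.02916	1.93	2.23	0
R19H	LRHASLG	6.5	1340.0	0.00485	2.62	3.29	0
RRASLG	RRASLG	17.9	26.0	0.68846	0.29	0.36	0
RASLG	RASLG	10.2	4400.0	0.00232	3.33	3.73	0
LRRASL	LRRASL	18.1	57.0	0.31754	0.75	0.82	0
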