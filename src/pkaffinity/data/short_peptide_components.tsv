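system	dg_mean	dg_sd	e_vdw_mean	e_vdw_sd	e_ele_mean	e_ele_sd	g_solv_mean	g_solv_sd	ddg_calc	ddg_sd
WT	-73.34	2.54	-38.83	2.26	-27.30	2.25	-7.22	1.95	0.00	2.54
RRASLG	-70.30	2.63	-35.71	2.61	-27.08	2.74	-7.52	2.10	3.04	2.63
RASLG	-53.14	2.35	-25.58	2.28	-21.55	2.41	-6.02	2.12	20.20	2.35
LRRASL	-63.13	2.67	-37.11	2.40	-17.63	2.63	-8.40	2.03	10.21	2.67
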