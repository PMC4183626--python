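system	dg_mean	dg_sd	e_vdw_mean	e_vdw_sd	e_ele_mean	e_ele_sd	g_solv_mean	g_solv_sd	ddg_calc	ddg_sd
WT	-73.34	2.54	-38.83	2.26	-27.30	2.25	-7.22	1.95	0.00	2.54
R18A	-52.79	2.39	-34.34	2.45	-12.16	2.21	-6.29	2.03	20.55	2.39
R19A	-28.66	1.94	-34.20	2.32	11.37	2.16	-5.83	2.06	44.68	1.94
R18K	-59.32	2.52	-35.46	2.07	-16.86	2.16	-5.91	2.22	14.02	2.52
R19K	-54.07	3.05	-41.52	2.16	-5.38	2.23	-7.16	1.99	19.27	3.05
R18Hd	-51.69	2.69	-40.52	2.46	-4.27	2.53	-6.90	2.05	21.65	2.69
R19Hd	-30.54	2.04	-39.29	2.15	15.67	2.19	-6.93	2.01	42.79	2.04
R18He	-58.33	2.35	-39.01	2.55	-12.05	2.21	-7.28	1.95	15.00	2.35
R19He	-29.14	2.57	-38.26	2.44	16.48	2.23	-7.36	1.99	44.20	2.57
R18Hp	-63.70	2.61	-36.47	2.66	-20.49	2.33	-6.74	2.01	9.63	2.61
R19Hp	-39.76	2.19	-36.62	2.15	3.49	2.21	-6.63	2.10	33.58	2.19
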