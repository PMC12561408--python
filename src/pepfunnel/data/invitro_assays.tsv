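id	sequence_recovery	pulldown	relative_expression	kd_m	spr	ec50_nm	t_half_h
D02	0.77	Success	0.95
D03	0.68	Success	0.86	7.83E-06	Success
D04	0.71	Success	0.91	7.73E-06	Success
D05	0.68	Fail
D06	0.71	Fail
D07	0.71	Fail
D08	0.74	Success	0.77	8.97E-05	Fail
D09	0.71	Success	0.84		Fail
D10	0.74	Fail
D11	0.68	Success	0.80	1.12E-05	Fail
D12	0.68	Fail
D13	0.81	Success	0.87	8.58E-06	Success	0.036	19.86
D14	0.74	Success	0.85	6.61E-05	Fail
D15	0.74	Fail
D16	0.71	Success	0.79
D17	0.74	Fail
D18	0.71	Fail
D19	0.71	Success	0.67
D20	0.74	Success	0.98
D21	0.68	Success	0.86
D22	0.74	Success	0.80
D23	0.71	Success	1.11	8.32E-06	Success
D24	0.71	Success	0.88
D25	0.74	Success	0.93
D26	0.74	Fail
D27	0.71	Fail
D28	0.77	Fail
D29	0.65	Fail
D30	0.65	Fail
D31	0.71	Success	0.87	4.79E-05	Fail
D32	0.74	Fail
D33	0.71	Success	0.82
D34	0.68	Fail
D35	0.71	Success	0.65
D36	0.68	Fail
D37	0.74	Success	0.74
D38	0.71	Fail
D39	0.71	Success	0.72	1.08E-04	Fail
D40	0.65	Fail
D41	0.74	Success	0.71	5.19E-06	Success	0.011	23.16
D42	0.68	Success	0.72
D43	0.74	Fail
D44	0.68	Success	0.76	6.78E-06	Success	0.012	4.19
D45	0.68	Fail
D46	0.65	Fail
D47	0.74	Fail
D48	0.74	Fail
D49	0.74	Success	0.70
D50	0.68	Success	0.63
D51	0.68	Success	0.73		Fail
D52	0.74	Fail
D53	0.71	Fail
D54	0.68	Fail
D55	0.65	Fail
D56	0.77	Success	0.73
D57	0.74	Success	0.55
D58	0.68	Fail
D59	0.74	Success	0.65
D60	0.71	Success	0.77
D61	0.71	Fail
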