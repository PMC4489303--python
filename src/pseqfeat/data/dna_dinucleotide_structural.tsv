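oligomer	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
Twist	0.06	1.50	0.78	1.07	-1.38	0.06	-1.66	0.78	-0.08	-0.08	0.06	1.50	-1.23	-0.08	-1.38	0.06
Tilt	0.5	0.50	0.36	0.22	-1.36	1.08	-1.22	0.36	0.5	0.22	1.08	0.50	-2.37	0.5	-1.36	0.5
Roll	0.27	0.80	0.09	0.62	-0.27	0.78	-0.44	0.09	0.27	1.33	0.78	0.80	-1.38	0.27	-0.27	0.27
Shift	1.59	0.13	0.68	-1.02	-0.86	0.22	-1.30	0.68	0.13	-0.35	0.22	0.13	-1.38	0.13	-0.86	1.59
Slide	0.11	1.29	-0.24	2.51	-0.62	-0.82	-0.29	-0.24	-0.39	0.65	-0.82	1.29	-1.01	-0.39	-0.62	0.11
Rise	-0.11	1.04	-0.62	1.17	-1.25	0.24	-0.58	-0.62	0.71	1.59	0.24	1.04	-1.39	0.71	-1.25	-0.11
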