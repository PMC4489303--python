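oligomer	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
Hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
Hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
SideChainMass	15.0	47.0	59.0	73.0	91.0	1.0	82.0	57.0	73.0	57.0	75.0	58.0	42.0	72.0	101.0	31.0	45.0	43.0	130.0	107.0
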