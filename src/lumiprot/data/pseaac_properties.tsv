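property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
mass	15.0	47.0	59.0	73.0	91.0	1.0	82.0	57.0	73.0	57.0	75.0	58.0	42.0	72.0	101.0	31.0	45.0	43.0	130.0	107.0
pK1	2.35	1.71	1.88	2.19	2.58	2.34	1.78	2.32	2.20	2.36	2.28	2.18	1.99	2.17	2.18	2.21	2.15	2.29	2.38	2.20
pK2	9.87	10.78	9.60	9.67	9.24	9.60	8.97	9.76	8.90	9.60	9.21	9.09	10.60	9.13	9.09	9.15	9.12	9.72	9.39	9.11
pI	6.11	5.02	2.98	3.08	5.91	6.06	7.64	6.04	9.47	6.04	5.74	5.41	6.30	5.65	10.76	5.68	5.60	6.02	5.88	5.63
rigidity	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
flexibility	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
irreplaceability	1.000	5.000	0.943	0.980	2.439	2.041	1.515	1.042	1.786	2.500	1.064	0.746	1.786	1.075	1.538	0.833	1.031	1.351	5.556	2.439
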