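residue	JACR890101	COWR900101	ZIMJ680103	MEEJ810102	FAUJ880110	WARP780101	PONP800108	LIFS790102
A	0.18	0.42	0.00	1.00	0.00	10.04	6.05	1.00
R	-5.40	-1.56	52.00	-2.00	3.00	6.18	5.70	0.68
N	-1.30	-1.03	3.38	-3.00	3.00	5.63	5.04	0.54
D	-2.36	-0.51	49.70	-0.50	4.00	5.76	4.95	0.50
C	0.27	0.84	1.48	4.60	0.00	8.89	7.86	0.91
Q	-1.22	-0.96	3.53	-2.00	3.00	5.41	5.45	0.28
E	-2.10	-0.37	49.90	1.10	4.00	5.37	5.10	0.59
G	0.09	0.00	0.00	0.20	0.00	7.99	6.16	0.79
H	-1.48	-2.28	51.60	-2.20	1.00	7.49	5.80	0.38
I	0.37	1.81	0.13	7.00	0.00	8.72	7.51	2.60
L	0.41	1.80	0.13	9.60	0.00	8.79	7.37	1.42
K	-2.53	-2.03	49.50	-3.00	1.00	4.40	4.88	0.59
M	0.44	1.18	1.43	4.00	0.00	9.15	6.39	1.49
F	0.50	1.74	0.35	12.60	0.00	7.98	6.62	1.30
P	-0.20	0.86	1.58	3.10	0.00	7.79	5.65	0.35
S	-0.40	-0.64	1.67	-2.90	2.00	7.08	5.53	0.70
T	-0.34	-0.26	1.66	-0.60	2.00	7.00	5.81	0.59
W	-0.01	1.46	2.10	15.10	0.00	8.07	6.98	0.89
Y	-0.08	0.51	1.61	6.70	2.00	6.90	6.73	1.08
V	0.32	1.34	0.13	4.60	0.00	8.88	7.62	2.63
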