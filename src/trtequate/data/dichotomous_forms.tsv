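form	item	testlet	anchor	a	b
reference	1		0	1.53	0.18
reference	2		0	2.32	-1.49
reference	3		0	1.04	-1.62
reference	4		0	1.71	0.89
reference	5		0	1.47	0.63
reference	6		0	1.68	-1.22
reference	7		0	1.49	-0.07
reference	8		0	1.48	-0.04
reference	9		0	2.20	-1.05
reference	10		0	1.13	-2.05
reference	11		0	1.04	-0.56
reference	12		0	1.11	-1.30
reference	13		0	1.28	0.78
reference	14		0	1.53	0.91
reference	15		0	1.35	0.67
reference	16		0	1.68	-1.58
reference	17		0	1.73	0.43
reference	18		0	1.64	0.65
reference	19		0	1.11	0.15
reference	20		0	1.85	-0.57
reference	21	1	0	1.09	1.35
reference	22	1	0	2.32	1.53
reference	23	1	0	1.52	0.97
reference	24	1	0	0.81	0.54
reference	25	1	0	1.25	1.05
reference	26	2	0	1.39	0.01
reference	27	2	0	1.91	-1.43
reference	28	2	0	1.48	1.76
reference	29	2	0	2.36	-0.44
reference	30	2	0	1.76	-0.61
reference	31	3	0	1.04	-1.05
reference	32	3	0	2.15	-0.86
reference	33	3	0	1.75	0.24
reference	34	3	0	1.35	-0.55
reference	35	3	0	1.78	0.66
reference	36	4	0	1.91	-0.99
reference	37	4	0	1.63	2.87
reference	38	4	0	1.12	-0.07
reference	39	4	0	1.23	-0.68
reference	40	4	0	0.75	0.11
reference	41	5	1	1.45	-0.59
reference	42	5	1	1.04	-0.17
reference	43	5	1	1.83	-1.19
reference	44	5	1	1.25	-1.62
reference	45	5	1	1.40	1.63
reference	46	6	1	1.52	-1.22
reference	47	6	1	1.42	-1.47
reference	48	6	1	1.53	-0.51
reference	49	6	1	1.92	1.68
reference	50	6	1	1.64	0.55
reference	51		1	1.37	-0.34
reference	52		1	1.56	0.61
reference	53		1	1.46	0.85
reference	54		1	1.58	0.32
reference	55		1	1.12	0.17
reference	56		1	1.62	-0.03
reference	57		1	1.94	0.20
reference	58		1	1.02	0.12
reference	59		1	1.53	0.50
reference	60		1	1.23	-0.93
new	1		0	1.45	-0.59
new	2		0	1.04	-0.17
new	3		0	1.83	-1.19
new	4		0	1.25	-1.62
new	5		0	1.40	1.63
new	6		0	1.52	-1.22
new	7		0	1.42	-1.47
new	8		0	1.53	-0.51
new	9		0	1.92	1.68
new	10		0	1.64	0.55
new	11		0	1.37	-0.34
new	12		0	1.56	1.67
new	13		0	1.46	0.85
new	14		0	1.58	0.32
new	15		0	1.12	0.17
new	16		0	1.62	-0.03
new	17		0	1.94	0.20
new	18		0	1.02	0.12
new	19		0	1.53	0.50
new	20		0	1.23	-0.93
new	21	1	0	1.52	1.64
new	22	1	0	1.67	-1.11
new	23	1	0	1.68	-1.11
new	24	1	0	1.70	-0.71
new	25	1	0	0.24	0.19
new	26	1	0	1.12	-0.45
new	27	1	0	1.43	0.62
new	28	1	0	0.68	-0.40
new	29	1	0	1.68	0.72
new	30	1	0	2.34	-1.86
new	31	2	0	1.74	-0.83
new	32	2	0	1.70	0.65
new	33	2	0	0.80	0.81
new	34	2	0	1.75	0.27
new	35	2	0	1.62	-0.19
new	36	2	0	1.72	0.87
new	37	2	0	0.31	-1.49
new	38	2	0	0.96	-0.38
new	39	2	0	1.24	0.02
new	40	2	0	1.78	0.17
new	41	3	1	1.46	-0.15
new	42	3	1	1.51	-0.64
new	43	3	1	1.87	1.10
new	44	3	1	1.67	0.27
new	45	3	1	1.53	-0.43
new	46	3	1	1.24	0.40
new	47	3	1	1.52	-1.53
new	48	3	1	1.52	-0.52
new	49	3	1	1.69	0.01
new	50	3	1	1.82	1.31
new	51		1	1.56	-1.62
new	52		1	1.46	-0.06
new	53		1	1.47	-0.35
new	54		1	1.61	0.86
new	55		1	1.42	-0.73
new	56		1	1.78	-0.84
new	57		1	2.00	-0.83
new	58		1	2.14	0.42
new	59		1	1.56	-0.39
new	60		1	1.80	-1.70
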