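form	item	testlet	anchor	a	b1	b2	b3	b4
reference	1		0	0.59	-0.03	0.27	0.50	0.56
reference	2		0	0.59	-2.45	-1.52	-0.96	0.10
reference	3		0	1.39	-1.38	-0.17	0.47	1.73
reference	4		0	1.20	-0.70	0.35	0.77	1.01
reference	5		0	1.31	-0.20	0.15	0.63	2.07
reference	6		0	0.88	-0.49	0.00	0.36	1.19
reference	7		0	0.83	-1.01	-0.46	-0.30	0.70
reference	8		0	0.68	-1.00	0.46	0.98	1.35
reference	9		0	1.17	-0.32	0.00	0.23	1.71
reference	10		0	1.36	-0.93	-0.76	-0.52	1.04
reference	11		0	1.28	-1.68	-0.99	-0.48	1.33
reference	12		0	0.74	-1.17	-0.73	-0.69	0.76
reference	13		0	1.26	-1.34	-1.15	0.22	0.52
reference	14		0	1.00	-0.58	-0.05	0.29	1.20
reference	15		0	1.37	-0.36	-0.09	0.81	1.02
reference	16		0	0.74	-1.86	-0.21	0.12	1.26
reference	17		0	0.80	-0.89	-0.32	0.37	0.73
reference	18		0	0.74	-1.67	-0.72	0.62	1.32
reference	19		0	1.31	-0.92	-0.65	0.41	1.66
reference	20		0	0.86	-1.04	-0.78	-0.15	1.28
reference	21	1	0	1.00	-0.59	0.16	0.20	0.64
reference	22	1	0	1.60	-0.79	-0.09	0.05	1.46
reference	23	1	0	1.03	-1.48	-0.64	-0.46	0.46
reference	24	1	0	0.59	-0.40	1.22	1.23	2.06
reference	25	1	0	0.89	-0.88	-0.40	1.03	2.53
reference	26	2	0	1.00	-1.29	-0.94	-0.38	0.77
reference	27	2	0	1.24	-2.03	-1.34	-0.05	0.59
reference	28	2	0	1.13	-0.88	-0.47	0.07	1.06
reference	29	2	0	0.60	-0.97	-0.67	-0.03	0.71
reference	30	2	0	0.97	-0.62	0.01	0.94	1.59
reference	31	3	0	1.23	-1.20	-1.01	0.64	0.80
reference	32	3	0	1.07	-0.36	-0.34	-0.32	0.54
reference	33	3	0	0.36	-1.04	-0.49	0.14	1.00
reference	34	3	0	0.76	-1.68	0.69	0.74	1.01
reference	35	3	0	0.90	0.45	0.72	1.16	1.69
reference	36	4	0	1.80	-1.81	0.14	0.96	1.19
reference	37	4	0	1.13	0.66	0.88	1.01	1.93
reference	38	4	0	1.26	-1.20	-0.15	0.44	0.79
reference	39	4	0	1.00	-2.07	0.09	0.11	0.19
reference	40	4	0	0.56	-1.26	-0.38	0.23	0.62
reference	41	5	1	1.21	-1.40	-1.17	-0.24	0.80
reference	42	5	1	1.12	-2.00	-0.72	0.05	0.06
reference	43	5	1	1.13	-1.02	-0.61	-0.35	0.15
reference	44	5	1	1.18	-1.07	-0.86	-0.19	0.44
reference	45	5	1	1.27	-1.17	-0.76	-0.20	1.60
reference	46	6	1	1.37	-0.67	-0.66	-0.35	0.18
reference	47	6	1	1.21	-2.63	-0.53	1.35	2.56
reference	48	6	1	1.21	-1.10	0.04	0.42	0.44
reference	49	6	1	1.01	-0.57	0.32	0.50	1.23
reference	50	6	1	1.46	0.13	0.90	0.96	1.01
reference	51		1	1.11	-0.01	0.92	1.58	2.47
reference	52		1	1.31	-0.92	-0.68	0.43	0.76
reference	53		1	1.59	-1.12	-1.09	-0.52	0.21
reference	54		1	1.74	0.22	0.37	1.14	1.14
reference	55		1	1.18	-0.15	0.54	0.86	0.92
reference	56		1	1.62	-0.53	-0.07	0.07	0.64
reference	57		1	1.20	-0.47	0.15	0.85	1.50
reference	58		1	1.22	-0.89	-0.21	0.52	0.66
reference	59		1	1.18	-0.90	-0.84	-0.75	0.75
reference	60		1	1.46	-1.62	-0.83	0.12	1.22
new	1		0	1.21	-1.40	-1.17	-0.24	0.80
new	2		0	1.12	-2.00	-0.72	0.05	0.06
new	3		0	1.13	-1.02	-0.61	-0.35	0.15
new	4		0	1.18	-1.07	-0.86	-0.19	0.44
new	5		0	1.27	-1.17	-0.76	-0.20	1.60
new	6		0	1.37	-0.67	-0.66	-0.35	0.18
new	7		0	1.21	-2.63	-0.53	1.35	2.56
new	8		0	1.21	-1.10	0.04	0.42	0.44
new	9		0	1.01	-0.57	0.32	0.50	1.23
new	10		0	1.46	0.13	0.90	0.96	1.01
new	11		0	1.11	-0.01	0.92	1.58	2.47
new	12		0	1.31	-0.92	-0.68	0.43	0.76
new	13		0	1.59	-1.12	-1.09	-0.52	0.21
new	14		0	1.74	0.22	0.37	1.14	1.14
new	15		0	1.18	-0.15	0.54	0.86	0.92
new	16		0	1.62	-0.53	-0.07	0.07	0.64
new	17		0	1.20	-0.47	0.15	0.85	1.50
new	18		0	1.22	-0.89	-0.21	0.52	0.66
new	19		0	1.18	-0.90	-0.84	-0.75	0.75
new	20		0	1.46	-1.62	-0.83	0.12	1.22
new	21	1	0	0.98	-1.18	-0.93	-0.66	1.25
new	22	1	0	1.06	-0.35	-0.19	0.37	0.87
new	23	1	0	0.35	-0.87	-0.42	0.42	0.98
new	24	1	0	0.79	-1.42	-0.90	-0.47	0.49
new	25	1	0	1.11	-0.30	-0.16	-0.16	0.61
new	26	1	0	1.29	-1.28	-0.97	-0.85	0.74
new	27	1	0	1.32	-0.87	-0.31	0.50	1.01
new	28	1	0	1.44	-1.04	0.27	0.71	1.54
new	29	1	0	0.47	-1.36	-0.81	-0.37	-0.16
new	30	1	0	1.11	0.13	0.41	1.10	1.32
new	31	2	0	0.71	-0.88	-0.03	0.06	0.42
new	32	2	0	0.85	-0.95	0.26	2.02	2.54
new	33	2	0	1.18	-1.08	-0.85	-0.07	0.56
new	34	2	0	1.08	-1.17	0.30	0.98	1.70
new	35	2	0	1.15	-1.24	-0.40	0.91	1.55
new	36	2	0	0.46	-0.70	-0.18	0.52	0.84
new	37	2	0	0.55	-2.01	-0.78	-0.38	-0.10
new	38	2	0	1.68	-1.45	-0.31	-0.22	0.22
new	39	2	0	0.90	-2.05	-0.59	1.51	1.60
new	40	2	0	1.98	-0.09	0.99	1.98	2.42
new	41	3	1	0.93	-1.19	-1.14	-0.15	0.23
new	42	3	1	1.57	-0.01	0.20	1.20	1.26
new	43	3	1	0.86	-2.01	0.25	0.75	1.07
new	44	3	1	0.69	-0.33	0.79	0.96	1.07
new	45	3	1	1.22	-0.94	-0.27	0.68	0.77
new	46	3	1	0.89	-0.94	-0.68	0.48	2.29
new	47	3	1	0.80	-1.19	-1.11	-0.40	0.19
new	48	3	1	1.30	-1.50	-1.03	-0.21	0.71
new	49	3	1	1.03	-0.39	0.28	0.29	0.35
new	50	3	1	1.11	-2.57	-1.05	-0.52	1.02
new	51		1	0.94	-1.57	0.05	0.51	0.90
new	52		1	0.64	-2.00	0.75	0.79	1.30
new	53		1	1.07	-0.61	-0.48	1.65	2.36
new	54		1	0.67	-0.47	0.00	0.10	0.35
new	55		1	1.36	0.52	0.59	1.17	1.24
new	56		1	0.97	-0.27	0.00	0.30	0.40
new	57		1	0.68	-2.02	-0.25	0.51	1.23
new	58		1	0.54	-0.69	-0.23	0.03	1.01
new	59		1	1.01	-1.74	-1.33	-1.30	0.54
new	60		1	0.70	-1.95	0.62	0.67	0.84
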