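seedling_id	mother	pollen_donor	diameter_mm	branch1_mm	branch2_mm	branch3_mm	branch4_mm	branch5_mm	mean_internode_mm	pool
52	Picual	Arbequina	42.12	3.28	3.20	2.93	2.13	1.95	2.70	SmaD
44	Picual	Arbequina	53.81	2.50	4.15	3.08	2.75	2.13	2.92	SmaD
49	Picual	Arbequina	53.48	2.75	2.33	1.95	2.35	2.43	2.36	SmaD
52	Picual	Arbequina	53.49	1.35	2.33	1.90	2.38	2.13	2.02	SmaD
38	Picual	Arbequina	48.00	1.68	0.90	1.05	0.63	1.00	1.05	SmaD
40	Picual	Arbequina	50.68	0.85	0.88	0.83	0.80	0.85	0.84	SmaD
39	Picual	Arbequina	106.52	1.15	1.63	0.70	1.18	1.10	1.15	LarD
44	Picual	Arbequina	105.25	0.88	1.65	1.93	1.45	1.80	1.54	LarD
59	Picual	Arbequina	110.83	1.85	1.68	1.10	1.50	1.50	1.53	LarD
50	Picual	Arbequina	92.81	1.43	1.38	1.50	0.95	1.15	1.28	LarD
59	Picual	Arbequina	101.92	1.63	1.53	1.80	2.05	1.68	1.74	LarD
45	Picual	Arbequina	59.83	1.73	2.13	1.18	1.63	1.05	1.54	SILe
60	Picual	Arbequina	77.72	1.20	1.63	1.10	1.35	1.50	1.36	SILe
46	Picual	Arbequina	87.76	0.88	1.50	2.03	1.80	1.98	1.64	SILe
42	Picual	Arbequina	42.24	1.95	1.75	1.13	1.38	1.15	1.47	SILe
47	Picual	Arbequina	66.02	1.55	1.25	0.88	1.58	0.73	1.20	SILe
49	Picual	Arbequina	90.15	1.55	1.25	1.33	1.83	1.35	1.46	SILe
50	Picual	Arbequina	85.91	2.80	2.43	2.15	2.00	1.55	2.19	LILe
47	Picual	Arbequina	92.45	2.30	3.13	2.73	2.38	1.73	2.45	LILe
53	Picual	Arbequina	86.37	2.58	2.48	2.73	2.38	2.10	2.45	LILe
59	Picual	Arbequina	108.65	2.53	1.80	1.95	1.85	1.83	1.99	LILe
62	Picual	Arbequina	119.19	2.43	2.93	2.03	2.00	2.90	2.46	LILe
3	Chiquitita	Arbosana	57.67	2.15	2.35	2.35	2.08	2.60	2.31	ChiCa
5	Chiquitita	Arbosana	72.23	2.13	1.93	2.48	2.18	2.50	2.24	ChiCa
4	Chiquitita	Arbosana	75.71	2.15	2.15	2.50	1.70	1.75	2.05	ChiCa
7	Chiquitita	Arbosana	67.78	2.00	2.20	2.13	2.00	2.03	2.07	ChiCa
2	Chiquitita	Arbosana	60.38	1.75	1.80	1.55	2.50	2.40	2.00	ChiCa
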