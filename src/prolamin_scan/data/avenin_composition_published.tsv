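amino_acid	A.1D	A.3D	A.Un	B.1D	B.3D	B.Un	C1.1D	C1.3D	C1.UN	C2.1D	C2.3D-a	C2.3D-b	C2.Un-a	C2.Un-b	D.3D	D.Un
Alanin	8.06	8.72	7.18	6.82	6.28	6.70	7.11	6.82	7.44	6.67	8.76	8.26	7.49	6.90	8.00	8.13
Cystein	4.27	4.62	4.31	3.64	3.59	3.57	3.16	3.03	3.31	3.14	3.69	3.48	3.52	3.07	8.57	6.25
Aspartic acid	0.47	0.51	0.48	0.91	0.90	0.89	0.79	0.76	0.41	0.78	0.46	0.87	0.88	0.77	0.57	0.63
Glutamic acid	1.42	1.54	1.44	2.27	2.24	2.23	1.98	2.27	2.07	2.35	2.76	2.61	2.20	2.30	1.71	1.25
Phenylalanin	4.27	3.08	4.31	6.36	6.28	5.80	3.56	3.41	4.13	7.84	7.37	7.83	6.61	7.66	4.57	3.75
Glycin	3.32	4.10	3.35	3.18	2.69	3.13	0.40	0.76	0.83	1.18	1.38	1.30	1.76	0.77	4.57	5.00
Histidin	1.42	1.54	1.44	0.91	0.90	0.45	0.79	0.76	0.83	0.78	1.84	0.87	0.44	0.77	1.71	1.88
Isoleucin	4.74	5.13	3.83	5.00	5.38	5.36	3.16	3.79	3.72	3.53	4.15	3.48	4.41	3.83	4.00	5.63
Lysin	1.42	1.03	1.44	0.45	0.45	0.45	1.19	1.14	1.24	0.78	0.92	0.87	0.88	0.77	1.14	1.25
Leucin	6.16	8.21	6.22	9.55	9.42	10.27	17.39	16.67	15.29	8.24	9.22	8.70	9.25	7.66	7.43	10.00
Methionin	9.48	9.74	9.57	5.91	5.83	4.91	2.77	2.65	2.48	1.96	2.30	2.17	2.64	1.92	6.29	6.25
Asparagin	0.95	1.03	0.96	0.45	0.45	0.45	0.79	0.76	0.83	0.78	0.92	0.87	0.88	0.77	1.14	1.25
Prolin	9.48	8.21	9.57	9.09	8.52	8.93	8.70	8.33	9.09	10.98	9.22	9.57	10.13	10.34	7.43	8.13
Glutamin	27.01	24.10	26.32	29.09	29.60	30.80	34.39	34.85	32.64	32.55	30.88	30.87	30.40	33.72	16.57	16.25
Arginin	2.84	3.59	2.87	2.73	3.14	2.68	1.58	1.89	2.07	2.35	2.76	2.61	2.64	2.30	3.43	3.75
Serin	2.37	3.08	2.87	2.73	3.59	2.68	3.16	2.65	2.89	1.57	1.84	1.74	2.20	1.92	5.71	3.75
Threonin	3.32	3.08	3.35	3.18	4.04	3.13	1.98	1.89	1.65	3.53	2.30	3.04	3.52	3.45	9.14	7.50
Valin	6.64	6.15	8.13	6.36	5.38	6.25	5.93	6.44	7.44	9.41	7.83	9.13	8.37	9.58	6.86	6.88
Tryptofan	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.63
Tyrosin	2.37	2.56	2.39	1.36	1.35	1.34	1.19	1.14	1.65	1.57	1.38	1.74	1.76	1.53	1.14	1.88
Total number of aminoacids	211	195	209	220	223	224	253	264	242	255	217	230	227	261	175	160
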