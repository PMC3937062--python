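identifier	sequence	nc_control	nc_treatment	mark
Vvi-miRC01	CTATGTTATAGGATCTTGGAT	9.16	17.19	↑
Vvi-miRC01*	CCAAGATACTATAACATGGTC	0.00	0.17	▲
Vvi-miRC02	TCCCTTTGGAAGTGCTAAGCG	0.00	1.83	▲
Vvi-miRC03	AGTGGTGGCAAGGATGAGCAA	0.00	0.52	▲
Vvi-miRC04	TTTGGAATGATTTGTTGATGA	4.62	1.48	↓
Vvi-miRC05	AAGATCTCCCATTGCATCTGA	0.00	0.52	▲
Vvi-miRC06	TTTTTTGGTTATGGTTGGCTG	0.61	1.40	↑
Vvi-miRC07	CTCAAGAAAGCTGTGGGAAAA	0.61	1.05	↑
Vvi-miRC07*	TTTCCACATCTTTCTTGAACT	0.09	0.17	●
Vvi-miRC08	AGAAGAACAAGTAGACTGAGC	0.00	0.96	▲
Vvi-miRC09	TTATATAGGCTTTGAGGATGGA	0.00	1.92	▲
Vvi-miRC10	TTTTAAAAAGGTTCGTCATTC	0.00	0.87	▲
Vvi-miRC11	CCGTGACAAGTGGTATCAGAG	0.00	1.13	▲
Vvi-miRC12	TCTGAAGTTTGAAGAGCTGTG	4.97	10.56	↑
Vvi-miRC12*	AGAGCAATCTACGAACAACAGGAA	0.09	0.09	●
Vvi-miRC13	TTGGCTTGGAGATGGATCATT	0.00	10.56	▲
Vvi-miRC14	TTGGCTTGGAGATGGATCATT	0.00	10.56	▲
Vvi-miRC15	TCAATTTGAGAGCTGGAAGAA	0.61	0.70	●
Vvi-miRC16	ATATTGGTAAATGAATGTTCG	0.00	1.40	▲
Vvi-miRC17	AATTTCTTATGTTCATGATTG	0.00	0.79	▲
Vvi-miRC18	AAGAGCAGTTGAACTGAAGCA	0.70	1.57	↑
Vvi-miRC19	TCTGTCGCAGGAGAGATGATGC	1.66	4.19	↑
Vvi-miRC20	GGAATGGGCTGATTGGGATA	2551.57	760.03	↓
Vvi-miRC20*	TTCCCAATGCCGCCCATTCCAA	94.07	208.55	↑
Vvi-miRC21	CCAAGAGGGTGGAGTTCAGAT	0.00	1.48	▲
Vvi-miRC21*	CTGAACTCTCTCCCTCATGGCC	0.00	0.87	▲
Vvi-miRC22	CTAAATTGCTTCGGGTCCTGC	0.00	6.63	▲
Vvi-miRC22*	AGGAGATGAGGTATGTTTACAT	0.00	5.93	▲
Vvi-miRC23	AAACATGAGTCTGGACCTTGA	0.00	0.79	▲
Vvi-miRC24	AAACATGAGTCTGGACCTTGA	0.00	0.79	▲
Vvi-miRC25	TCTGTTTTCACTCTCATTAAG	0.00	1.13	▲
Vvi-miRC25*	TAGTGAGAATGAGTTGGGGAAG	0.00	0.09	▲
Vvi-miRC26	TCGGAGAAGTGTGATGTGTAT	0.00	0.70	▲
Vvi-miRC27	ATACCATGTGGAAAAGAGGAATC	6.72	5.85	●
Vvi-miRC28	ATTGGCAGAATATTCAAGGTTT	0.44	0.87	↑
Vvi-miRC29	TTATTAGGAGGACATTTAGGTAT	2.88	3.49	●
Vvi-miRC30	TGCGGGTGGAAGAGAAGGAAG	5.67	3.49	↓
Vvi-miRC31	TTCCTGCGGTTTCTCGGCGAC	0.96	0.96	●
Vvi-miRC32	TTTTCCTATGATTTCTTGGCA	0.87	0.79	●
Vvi-miRC32*	CTGGGAAAGCGTGGGAAAACA	0.00	0.09	▲
Vvi-miRC33	TTCCTATCGTTCCCGGGATTT	0.00	1.22	▲
Vvi-miRC34	TGACCGGCTCTTATCTCTCATG	1.48	3.93	↑
Vvi-miRC34*	TGAAGATAAAGAGTCTCGTCTGG	0.35	0.09	↓
Vvi-miRC35	GGAATGGATGGCATGGGAACCA	0.52	0.52	●
Vvi-miRC36	TGAGTAGTGGACTATCGCATG	14.57	1728.01	↑
Vvi-miRC36*	TGAGATAAGTCTGCTGCTCCAT	0.61	94.76	↑
Vvi-miRC37	TGGATGCATGTAGCTTGTCAA	16.06	0.87	↓
Vvi-miRC37*	GACAAGTTACATACATCCAAG	1.05	0.17	↓
Vvi-miRC38	TCCTTCGGCGTCGGCAAATCC	1.75	1.22	↓
Vvi-miRC39	AAGGGTTTCTCACAGAGTTTA	0.00	0.79	▲
Vvi-miRC39*	AGCTCTGTTGGACTCTCTTTG	0.00	0.17	▲
Vvi-miRC40	GAGGAGAATGTAGTGGGGTTA	0.52	0.44	●
Vvi-miRC41	CTTTGATCAGATATTGGATTG	0.00	1.40	▲
Vvi-miRC41*	AGCAGAGTTTGATAGAGGGC	0.00	0.09	▲
Vvi-miRC42	AATGACATGAGTTGGAACTAA	0.00	0.87	▲
Vvi-miRC43	GTTGGAAGCCGGTGGGGGACC	4389.70	425.65	↓
Vvi-miRC44	GTTGGAAGCCGGTGGGGGACC	4389.70	425.65	↓
Vvi-miRC45	GTTGGAAGCCGGTGGGGGACC	4389.70	425.65	↓
Vvi-miRC46	GTTGGAAGTCGGTGGGGGAAC	1990.92	272.69	↓
Vvi-miRC47	GGCGATTGTAAATATGGGTAA	3.75	1.13	↓
Vvi-miRC48	TCTAGATTTGGAAGTAGGTCA	0.70	0.44	●
Vvi-miRC49	GTTGGAAGTCGGTGGGGGACC	1089.01	72.95	↓
Vvi-miRC50	GTTGGAAGCCGGTGGGGGACC	4389.70	425.65	↓
Vvi-miRC51	TGGGCTTGTGGAGAAGAAAGTGA	0.96	0.52	↓
Vvi-miRC52	CATGGGCGGTTTGGTAAGAGG	2805.93	1401.92	↓
Vvi-miRC52*	TCTTACCAACACCTCCCATTCC	140.49	198.43	↑
Vvi-miRC53	GGTATGGGAGGATTGGGGAGA	1305.32	437.43	↓
Vvi-miRC53*	TTCCCAAGACCCCCCATGCCAA	62.48	327.23	↑
Vvi-miRC54	TCATACCTCGATCTTCGGTTTC	0.00	0.70	▲
Vvi-miRC54*	AATCTGAGATCGAGAATGAAA	0.00	0.09	▲
Vvi-miRC55	ATTCGAACTCAAGACTAAGGT	0.00	41.54	▲
Vvi-miRC56	GAAGCTCTTGAGGGGGACTG	378.18	60.38	↓
Vvi-miRC56*	ACTCTCCCTCAAGGGCTTCTG	12.13	1.31	↓
Vvi-miRC57	AGGTGTAGATGCAAGTGCAGA	0.00	1.05	▲
Vvi-miRC58	TTTAATTTACTAGAGATCTCT	1.13	1.40	●
Vvi-miRC59	GGAGTGAAATTGCAGTGACGG	0.00	1.13	▲
Vvi-miRC60	TCAGCAGGAATTGGACCAGAA	2.88	3.75	●
Vvi-miRC61	ACAGTAGGAAATTGAAAGAGA	0.00	0.70	▲
Vvi-miRC61*	TCTTTCATTTTCCTACTTTTT	0.00	0.52	▲
Vvi-miRC62	AAAGGCGAAGAAAAAGAAGATA	1.75	0.79	↓
Vvi-miRC63	AATATGGAGGACTGTGTTCTT	0.61	1.75	↑
Vvi-miRC63*	GAACTCAGTTCCGGTACCATCTTCA	0.09	0.09	●
Vvi-miRC64	TTGGATTCGCGCACAAACTCG	0.00	1.13	▲
Vvi-miRC65	TTGGATTCGCGCACAAACTCG	0.00	1.13	▲
Vvi-miRC66	CAGCAGTTGCTATTGTGGTTG	0.87	8.38	↑
Vvi-miRC67	AGAAGAGAGAGAGTACAGCTA	1.31	9.60	↑
Vvi-miRC68	TGGTACCAGGAGGGCAACTGTC	0.00	1.05	▲
Vvi-miRC68*	TGTTGCCCTCCTGGTACCATC	0.00	0.09	▲
Vvi-miRC69	TCAAGGGTCGAACGGCTTTGC	1.31	2.36	↑
Vvi-miRC70	TTATGTGAGTGTTCGGCAAATC	0.79	2.62	↑
Vvi-miRC71	TTAGATGATCATCAACAAACA	436.74	517.54	●
Vvi-miRC71*	TTTTGTTGCTGGTCATCTAGTC	2.09	3.05	●
Vvi-miRC72	TGCTTATTAGGTCTGCTGGCA	0.00	0.61	▲
Vvi-miRC73	TCAAAAGAGAAAATGTGGATG	0.52	0.79	●
Vvi-miRC73*	TCCATCTTCTCTCTTTTTACA	0.00	0.09	▲
Vvi-miRC74	TCGCAGGAGAGATGACGCCGT	52.97	110.21	↑
Vvi-miRC74*	AGCATCATTTCTCCTGCATAG	1.13	4.28	↑
Vvi-miRC75	ATATTAGCAGCTGAGAACACA	1.40	0.00	▼
Vvi-miRC76	CAGGACTGGCAGTGATGGTTA	1.13	0.00	▼
Vvi-miRC77	GTGTTTTGCAGGATCAGACGG	0.70	0.00	▼
Vvi-miRC78	TGGCTGAGAACTTGATGGTTA	2.71	0.00	▼
Vvi-miRC79	TTCAAGTCAAAGTCGAACAAG	0.87	0.00	▼
Vvi-miRC80	AGCGAAGTAGTTGTAGGGCTT	0.96	0.00	▼
Vvi-miRC81	TTCGGAGGGAACTGACCGGTT	0.70	0.00	▼
Vvi-miRC82	TGCCAAGAAGCACATTCCTCC	16.84	0.00	▼
Vvi-miRC82*	AGGAATGTGCTTCTTGGCATA	0.09	0.00	▼
Vvi-miRC83	CAAGTGTGGGATTTTGGGTGGCT	0.52	0.00	▼
Vvi-miRC84	GCAGCATCATGAAGATTCACA	0.52	0.00	▼
Vvi-miRC84*	GGAATCTTGATGATGCTGCAT	0.17	0.00	▼
Vvi-miRC85	AGGTGCAGGTGAAGGTGCAGA	1.75	0.00	▼
Vvi-miRC85*	TGCATTTGCACCTGCACCTTA	0.96	0.00	▼
Vvi-miRC86	GTAGCATCATCAAGATTCACA	1.66	0.00	▼
Vvi-miRC87	GGAATGTTGTCTGGCTCGAGGT	0.70	0.00	▼
Vvi-miRC88	ATGTATTTGAGGGAAAGCAAA	0.44	0.00	▼
Vvi-miRC88*	TGTTTTCCCTCAAAAACATGT	0.09	0.00	▼
Vvi-miRC89	CTGCGGGTGGAAAAGGATTAGGC	6.81	0.00	▼
Vvi-miRC89*	CTCATCCTTTTCCATCGGCAGCA	0.35	0.00	▼
Vvi-miRC90	TCTCAGCAACCAAGTAGAGCC	5.93	0.00	▼
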