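identifier	sequence	nc_control	nc_treatment	mark
Vvi-miR156a	TTGACAGAAGAGAGGGAGCAC	8.81	513.79	↑
Vvi-miR156b	AACTGACAGAAGAGAGTGAGCAC	2308.90	0.61	↓
Vvi-miR156c	TGACAGAAGAGAGTGAGCACAC	2214.31	0.17	↓
Vvi-miR156d	TGACAGAAGAGAGTGAGCAC	2321.38	2331.59	●
Vvi-miR156e	TGACAGAGGAGAGTGAGCAC	3.40	14.83	↑
Vvi-miR156f	CTGTTGACAGAAGATAGAGAGCAC	5215.88	3.93	↓
Vvi-miR156g	GCTCTCTAGACTTCTGTCATC	5214.31	0.61	↓
Vvi-miR156i	TTGACAGAAGATAGAGAGCAC	5214.31	6093.28	↑
Vvi-miR159b	CCTTGGAGTGAAGGGAGCT	0.00	0.17	▲
Vvi-miR159c	TTTGGATTGAAGGGAGCTCTA	74.61	582.11	↑
Vvi-miR160a	TCCTAGTTGGCATCAGAGGAG	1.66	0.09	↓
Vvi-miR160b	GCATGAGGGGAGTCAAGCAGG	1.66	4.19	↑
Vvi-miR160c	GCGTGCGAGGAGCCAAGCATA	3.75	4.54	●
Vvi-miR160d	TGCCTGGCTCCCTGTATGCCA	4.71	0.00	▼
Vvi-miR160e	GCGTATGAGGAGCCATGCATA	4.71	2.27	↓
Vvi-miR160f	TGCCTGGCTCCCTGTATGCCA	0.00	43.98	▲
Vvi-miR162	TCGATAAACCTCTGCATCCAG	236.04	231.76	●
Vvi-miR164a	TTGGAGAAGCAGGGCACGTGC	43.02	0.17	↓
Vvi-miR164c	TGGAGAAGCAGGGCACGTGCAT	43.19	6.72	↓
Vvi-miR164d	TGGAGAAGCAGGGCACGTGCA	43.02	798.08	↑
Vvi-miR166a	TCTCGGACCAGGCTTCATTCCT	762.04	7.85	↓
Vvi-miR166b	TCGGACCAGGCTTCATTCCTC	3280.28	15371.38	↑
Vvi-miR166c	TCGGACCAGGCTTCATTCCCC	21467.36	0.00	▼
Vvi-miR166d	GATTGTTGTCTGGCTCGAGGC	21492.15	1.05	↓
Vvi-miR166e	GGAATGTTGTCTGGCTCGAGG	21467.36	311.87	↓
Vvi-miR166f	GGAATGTTGGCTGGCTCGAGG	21506.81	18.24	↓
Vvi-miR166g	TTCGGACCAGGCTTCATTCCC	21509.60	82.11	↓
Vvi-miR166h	TCGGACCAGGCTTCATTCCCC	22171.73	22520.68	●
Vvi-miR167a	TGAAGCTGCCAGCATGATCTGG	32.81	11.78	↓
Vvi-miR167b	TGAAGCTGCCAGCATGATCTAAG	616.06	38.48	↓
Vvi-miR167c	TGAAGCTGCCAGCATGATCTC	134.12	1901.57	↑
Vvi-miR167d	TGAAGCTGCCAGCATGATCTAG	424.87	1.75	↓
Vvi-miR167e	TGAAGCTGCCAGCATGATCTA	613.09	2349.30	↑
Vvi-miR168	TCGCTTGGTGCAGGTCGGGAA	2963.35	2654.62	●
Vvi-miR169a	CAGCCAAGGATGACTTGCCGG	13.09	0.00	▼
Vvi-miR169b	GGTCGAATTGAGCCAAGGATGG	5.58	0.35	↓
Vvi-miR169c	TCCGGCAAGTTGTCCTTGGCTAC	13.09	0.70	↓
Vvi-miR169d	CAGCCAAGAATGATTTGCCGG	35.25	105.50	↑
Vvi-miR169e	TAGCCAAGGATGACTTGCCT	0.44	0.00	▼
Vvi-miR169f	TGGGCAAGTTGTGTTTGGCTAC	0.35	0.26	●
Vvi-miR169g	CAGCCAAGGATGACTTGCCGA	0.44	6.54	↑
Vvi-miR169h	TGAGCCAAGGATGGCTTGCCGT	5.50	7.42	●
Vvi-miR169i	CTGGTCATGCACGGCTGGTTA	1.83	0.09	↓
Vvi-miR169j	CAGCCAAGGATGACTTGCCGG	13.09	0.00	▼
Vvi-miR169k	AGCCAAGGATGACTTGCCGGA	13.09	0.26	↓
Vvi-miR169l	TGAGCCAAGGATGACTTGCCGT	58.12	0.96	↓
Vvi-miR169m	TGAGCCAAGGATGACTTGCCG	54.45	0.00	▼
Vvi-miR169n	AAGCATCTGAGGCTCTATTTC	16.32	186.82	↑
Vvi-miR169o	TGAGCCAAGGATGACTTGCCG	54.80	13.53	↓
Vvi-miR169p	GCAAGCATCCGAGGCTCTGT	55.50	3.66	↓
Vvi-miR169q	TAGAGCCAAGGATGACTTGCCG	16.40	6.37	↓
Vvi-miR169r	TGAGTCAAGGATGACTTGCCGA	4.71	0.79	↓
Vvi-miR169s	CAGCCAAGGATGACTTGCCGG	13.18	0.00	▼
Vvi-miR169t	GGCAAGTTGACTTGACTCAGT	1.66	6.81	↑
Vvi-miR169u	GGCAAGTTGACTTGACTCTGT	2.71	4.01	●
Vvi-miR169v	AAGCCAAGGATGAATTGCCGG	4.36	2.62	↓
Vvi-miR169w	CAGCCAAGGATGACTTGCCGG	13.18	12.39	●
Vvi-miR169x	TGAGTCAAGGATGACTTGCCGA	0.52	0.70	●
Vvi-miR171a	TGTTGGGACGGCTCAATCAAA	4.71	5.67	●
Vvi-miR171b	TTGAGCCGCGTCAATATCTCC	4.36	35.69	↑
Vvi-miR171c	GGATATTGGTGCGGTTCAATA	5.15	4.54	●
Vvi-miR171d	TTGATTGAGCCGTGCCAATAT	5.15	2.53	↓
Vvi-miR171e	TGATTGAGCCGCGCCAATATC	0.00	0.09	▲
Vvi-miR171f	TTGAGCCGCGCCAATATCACT	0.00	2.01	▲
Vvi-miR171h	TTGAGCCGCGCCAATATCCCG	0.00	0.96	▲
Vvi-miR171i	TGATTGAGCCGTGCCAATATC	4.71	85.43	↑
Vvi-miR172c	GGAGCATCATCAAGATTCACA	0.09	103.40	↑
Vvi-miR172d	AGAATCTTGATGATGCTGCAT	184.47	117.63	↓
Vvi-miR319b	TTGGACTGAAGGGAGCTCCC	0.35	0.00	▼
Vvi-miR319c	ATTGAATGATGCGGGAGACAA	0.35	20.68	↑
Vvi-miR319e	TTTGGACTGAAGGGAGCTCCT	18.59	7.94	↓
Vvi-miR319f	TGCTTGGACTGAAGGGAGC	0.35	3.40	↑
Vvi-miR319g	TTGGACTGAAGGGAGCTCCC	0.26	1.40	↑
Vvi-miR390	AAGCTCAGGAGGGATAGCGCC	1.75	160.73	↑
Vvi-miR393a	ATCATGCTATCCCTTAGGAAC	0.00	1.66	▲
Vvi-miR393b	GGAGGAGGCATCCAAAGGGAT	0.00	0.79	▲
Vvi-miR394a	TTGGCATTCTGTCCACCTCC	2.71	0.00	▼
Vvi-miR394b	TATTGGCATTCTGTCCACCTCC	2.53	0.09	↓
Vvi-miR394c	TTGGCATTCTGTCCACCTCC	2.71	0.79	↓
Vvi-miR395a	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395b	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395c	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395d	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395e	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395f	CACTGAAGTGTTTGGGGGAAC	22.08	0.09	↓
Vvi-miR395g	GTTCCCCTGAGCACTTCATTG	22.16	0.52	↓
Vvi-miR395h	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395i	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395j	CTGAAGTGTTTGGGGGAACTC	22.08	0.00	▼
Vvi-miR395k	GTTCCCTTGACCACTTCACTG	22.08	0.44	↓
Vvi-miR395l	CCCCTAGAGTTCCCCTGACCA	22.08	0.09	↓
Vvi-miR395m	CTGAAGTGTTTGGGGGAACTC	22.08	11.61	↓
Vvi-miR396a	CTCAAGAAAGCTGTGGGAGG	25.04	35.17	↑
Vvi-miR396b	TTCCACAGCTTTCTTGAACTT	53.23	35.86	↓
Vvi-miR396c	TTCCACAGCTTTCTTGAACTG	13.53	18.41	↑
Vvi-miR396d	GTTCAATAAAGCTGTGGGAAG	14.22	6.20	↓
Vvi-miR397a	TCATTGAGTGCAGCGTTGATG	7.59	29.41	↑
Vvi-miR398a	CAAGGGAGTGGCACCTGAGAACA	0.09	6.98	↑
Vvi-miR398b	GGTGTGACCTGAGAATCACATG	0.61	0.26	↓
Vvi-miR398c	TGTGTTCTCAGGTCGCCCCTG	0.61	1.13	↑
Vvi-miR399a	GTGTGATTCTCCTTTGGCAGA	0.70	1.57	↑
Vvi-miR399b	TGCCAAAGGAGAGTTGCCCTG	0.26	0.00	▼
Vvi-miR399c	TGCCAAAGGAGAGTTGCCCTG	0.26	0.09	↓
Vvi-miR399d	TCTGCCAAAGGAGATTTGCTC	1.48	0.26	↓
Vvi-miR399e	TGCCAAAGGAGATTTGCCCGG	3.58	10.56	↑
Vvi-miR399g	TGCCAAAGGAGATTTGCCCCT	9.08	1.31	↓
Vvi-miR399h	TGCCAAAGGAGAATTGCCCTG	0.52	0.96	↑
Vvi-miR399i	CGCCAAAGGAGAGTTGCCCTG	29.49	14.05	↓
Vvi-miR403a	TTAGATTCACGCACAAACTCG	52.27	0.00	▼
Vvi-miR403b	TTAGATTCACGCACAAACTCG	52.62	0.00	▼
Vvi-miR403c	CGCACAAACTCGTGATCTGTC	52.27	0.09	↓
Vvi-miR403d	AGTTTGTGCGCGAATCCAACC	52.62	4.36	↓
Vvi-miR403e	TTAGATTCACGCACAAACTCGC	52.18	0.17	↓
Vvi-miR403f	TTAGATTCACGCACAAACTCG	52.36	586.04	↑
Vvi-miR408	ACGGGGACGAGGTAGTGCATG	22.34	62.04	↑
Vvi-miR477	TCCCTCAAAGGCTTCCAATTT	98.25	21.82	↓
Vvi-miR479	TGTGGTATTGGTTCGGCTCATC	2922.60	1131.41	↓
Vvi-miR482	AATTGGAGAGTAGGAAAGCTT	45.11	1056.46	↑
Vvi-miR535a	TGACAACGAGAGAGAGCACGC	763.18	0.00	▼
Vvi-miR535b	ACGAGAGAGAGCACGCTAGTCAG	763.18	0.09	↓
Vvi-miR535c	TGACAACGAGAGAGAGCACGC	763.18	83.42	↓
Vvi-miR828a	AGATGCTCATTTGAGGAAGCAA	1.13	5.32	↑
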