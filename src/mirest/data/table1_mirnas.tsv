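family	ref_id	precursor_length	mfe	mature_seq	n_mismatch	mature_length	source_est	arm	gc_percent	strand	organ
vun-mir398	mtr-mir398a	131	-32.24	TGTGTTCTCAGGTCGCCCCTG	2	21	FF542932	5'	61.90	+	leaves
vun-mir413	ath-mir413	353	-88.55	TTAGTTTCTCTTGTTCTGCTT	2	21	FG940215	5'	33.33	+	mixed
vun-mir435	osa-mir435	347	-124.38	TTATGAGGCTTTGGAGTTGA	4	20	FG811172	3'	40.00	+	mixed
vun-mir834	ath-mir834	135	-52.95	TGGTAGCAGTGGCGGTGGTGG	3	21	FG822669	3'	66.66	-	mixed
vun-mir1512	gma-mir1512a	46	-10.60	CCTTTAAGAATTTCA-TTA--	4	18	FG880488	3'	22.22	-	mixed
vun-mir1514	gma-mir1514	127	-31.70	TTCATTTCTAAAATAGGCATC	2	21	FF388166	5'	28.57	-	root
vun-mir1525	gma-mir1525	78	-14.10	GGGGTTAAATATGTTTTTAGT	3	21	FG845219	5'	28.57	+	mixed
vun-mir1848	osa-mir1848	77	-32.20	CGCTCGCCGGCGCGCGCGTCCA	2	22	FG920123	3'	86.36	+	mixed
vun-mir2095	osa-mir2095	57	-17.20	CTTCCATTTATGACATGTTT	3	20	FG838629	5'	30.00	-	mixed
vun-mir2606	mtr-mir2606a	69	-13.00	TTGAAGTGCTTGGTTCTCACT	4	21	FG931806	5'	42.85	+	mixed
vun-mir2609	mtr-mir2609a	70	-13.00	TTGAAGTGCTTGGTTCTCACT	4	21	FG931806	5'	42.85	+	mixed
vun-mir2622	mtr-mir2622	210	-36.85	CTTGTGTGCCATTGTGAGCTTA	3	22	FG900047	3'	45.45	-	mixed
vun-mir2630	mtr-mir2630a	114	-24.70	TGGTTTTGGTCTTTGGTTTTA	3	21	FF391380	5'	33.33	+	root
vun-mir2636	mtr-mit2636	191	-29.40	GGATGTTAGTGTGCTGAATAT	4	21	FG814033	5'	38.09	-	mixed
vun-mir2657	mtr-mir2657	156	-35.38	TTTTATTGTATTGATTTTGTTG	4	22	FG926034	5'	18.18	-	mixed
vun-mir2678	mtr-mir2678	136	-39.32	TAAAGTTGTTGCGCGTGTC	3	19	FF389500	3'	47.36	-	root
vun-mir2950	mes-mir2950	347	-83.20	TTCCATCTCTTGCAGACTGAA	2	21	FG872933	5'	42.85	-	mixed
vun-mir3434	ath-mir3434	78	-17.40	TGAGAGTATCAGCCATGAGA	2	20	FF392538	3'	45.00	-	root
vun-mir4351	gma-mir4351	148	-63.30	GTTAGGGTTCAGTTGGAGTTGG	3	22	FG936300	3'	50.00	-	mixed
vun-mir4392	gma-mir4392	306	-80.53	TCTGTGAGAACGTGATTTCGGA	3	22	FG857306	5'	45.45	+	mixed
vun-mir4408	gma-mir4408	66	-20.70	CAACAACATTGGATGAGTATAGGA	4	24	FG894682	3'	37.5	+	mixed
vun-mir4414a	mtr-mir4414a	120	-42.20	AGCTGCTGACTCGTTGGTTCA	0	21	FF537171	5'	52.38	+	leaves
vun-mir4414b	mtr-mir4414a	120	-42.20	ATTCAACGATGCGGGAGCTGC	1	21	FF537171	3'	57.14	+	leaves
vun-mir4992	gma-mir4992	63	-21.20	CATCTAAGATGGTTTTTTTCAG	4	22	FG926352	3'	31.81	-	mixed
vun-mir4996	gma-mir4996	163	-49.83	TAGAAGTTACCCATGTTCTC	2	20	FF388735	3'	40.00	-	root
vun-mir5012	ath-mir5012	172	-43.44	TTTTGCTGCTCCGTGTGTTCC	3	21	FG809429	3'	52.38	+	mixed
vun-mir5043	gma-mir5043	125	-48.20	CTTCTCCTTCTCTGCACCACC	3	21	FG810406	5'	57.14	+	mixed
vun-mir5215	mtr-mir5215	181	-49.63	AGGAGGATGAGCTAGTTGATT	3	21	FG939979	5'	42.85	+	mixed
vun-mir5216	mtr-mir5216a	124	-27.58	TTGGGAGTGAAAAACAGTGGAA	2	22	FF399948	5'	40.90	+	root
vun-mir5219	mtr-mir5219	107	-25.23	TCATGGAATCTCAGCTGCAGCAG	1	23	FG850600	3'	52.17	-	mixed
vun-mir5227	mtr-mir5227	140	-18.04	AGAACAGAAGAAGATTGAAGAA	3	22	FG915684	5'	31.81	-	mixed
vun-mir5241	mtr-mir5241a	381	-119.80	TGGGTGAATGGAAGAGTGAAT	3	21	FG904590	3'	42.85	+	mixed
vun-mir5246	mtr-mir5246	68	-18.70	CACCAGAGAGCTTTGAAGGTT	4	21	FG856911	3'	47.61	+	mixed
vun-mir5255	mtr-mir5255	54	-10.40	TGACAGGATAGAGGACATGAC	4	21	FG910302	5'	47.61	-	mixed
vun-mir5261	mtr-mir5261	311	-71.81	CGATTGTAGATGGCTTTGGCT	3	21	FG838847	5'	47.61	-	mixed
vun-mir5280	mtr-mir5280	90	-20.22	TAAGTAGAAACGGGCCGAGATCGGGG	4	26	FG915361	5'	57.69	-	mixed
vun-mir5290	mtr-mir5290	217	-30.24	AAAGTAGAGAGAGAAAGACACATA	4	24	FG852502	5'	33.33	+	mixed
vun-mir5298	mtr-mir5298a	192	-36.58	TGGATTTCAAGATGAAGATGAAGAA	4	25	FF402284	3'	32.00	-	root
vun-mir5376	gma-mir5376	341	-132.02	TGGAGATTGTGAAGAATTTGAGA	3	23	FG872123	3'	34.78	+	mixed
vun-mir5561	mtr-mir5561	346	-69.34	ATCTCTCTCTCTCTAAATGTA	3	21	FF390124	5'	33.33	-	root
vun-mir5758	mtr-mir5758	91	-22.60	TAAGTTGGATCTATGTATTTG	3	21	FG893334	3'	28.57	+	mixed
vun-mir5770	gma-mir5770a	98	-30.40	TTAGGACTATGGTTTGGATGA	1	21	FG937135	3'	38.09	-	mixed
vun-mir6252	osa-mir6252	90	-20.90	ATGAGTTGTGTTGAGAGAGGGTT	4	23	FG841373	3'	43.47	-	mixed
vun-mir7696	mtr-mir7696a	173	-33.67	ACAAGTACTTA-AATTCAAAA	4	20	FG864277	3'	20.00	-	mixed
vun-mir8182	ath-mir8182	170	-31.80	TTGTGTTGCGTTTGTGATGACT	3	22	FG942892	5'	40.90	-	mixed
vun-mir9748	gma-mir9748	98	-32.45	GAAGGAAGTGTTGAGGGAGGAG	3	22	FG921211	5'	54.54	+	mixed
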