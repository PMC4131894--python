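family	name	ref_name	sequence	length	leaf	bark	male_flower	ath	gma	mdm	ptc	rco	osa	zma
miR156	mno-miR156a	zma-miR156g-3p	GCTCACTTCTCTTTCTGTCAGC	22	0	46	4	-	-	-	-	-	++	++
miR156	mno-miR156b	gma-miR156f	TTGACAGAAGAGAGAGAGCACA	22	6	2	337	+	++	+	+	+	+	+
miR156	mno-miR156c	gma-miR156m	TTGACAGAAGATAGAGAGCAC	21	12787	117270	768488	++	++	++	++	+	+	+
miR156	mno-miR156d	gma-miR156o	TTGACAGAAGAGAGTGAGCAC	21	2942	14574	8723	-	++	+	+	+	-	+
miR156	mno-miR156e	mdm-miR156w	TTGACAGAAGAGAGAGAGCAC	21	2099	1277	155199	+	++	++	+	+	+	+
miR156	mno-miR156f	ssl-miR156	TGACAGAAGAGAGTGAGCACA	21	22	378	65	-	+	+	+	++	-	+
miR156	mno-miR156g	tcc-miR156a	TGACAGAAGAGAGAGAGCACA	21	8	4	1198	+	++	+	-	++	++	++
miR159	mno-miR159a	ssp-miR159a	TTTGGATTGAAGGGAGCTCTG	21	3624	4571	3146	+	+	+	+	+	++	++
miR159	mno-miR159b	aly-miR159c-3p	TTTGGATTGAAGGGAGCTCCT	21	31	29	0	++	+	+	+	+	+	+
miR160	mno-miR160a	aly-miR160a-3p	GCGTATGAGGAGCCATGCATA	21	596	428	2345	-	+	-	++	-	-	-
miR160	mno-miR160b	cme-miR160c	TGCCTGGCTCCCTGTATGCCA	21	11	14	13	++	++	++	++	++	++	++
miR162	mno-miR162	cme-miR162	TCGATAAACCTCTGCATCCAG	21	578	956	727	++	++	++	++	++	++	+
miR164	mno-miR164a	cme-miR164d	TGGAGAAGCAGGGCACGTGCA	21	10734	6078	1191	++	++	++	++	++	++	++
miR164	mno-miR164b	vun-miR164	TGGAGAAGGGGAGCACGTGCA	21	21	0	12	+	+	+	+	+	+	+
miR166	mno-miR166a	hbr-miR166b	TCGGACCAGGCTTCATTCCCCC	22	26	51	27	-	+	+	+	+	-	-
miR166	mno-miR166b	cme-miR166a	TCGGACCAGGCTTCATTCCCC	21	198685	238486	252806	-	++	++	++	++	-	-
miR166	mno-miR166c	gma-miR166k	TCTCGGACCAGGCTTCATTCC	21	20100	168078	39124	-	++	+	-	+	-	-
miR166	mno-miR166d	gma-miR166l	GGAATGTTGTCTGGCTCGAGG	21	3935	975	901	-	++	-	-	-	++	++
miR166	mno-miR166e	osa-miR166g-3p	TCGGACCAGGCTTCATTCCTC	21	91	241	121	-	+	+	+	+	++	++
miR166	mno-miR166f	bdi-miR166e	CTCGGACCAGGCTTCATTCCC	21	31	56	194	-	+	+	-	+	-	-
miR166	mno-miR166g	zma-miR166m-5p	GGAATGTTGGCTGGCTCGAGG	21	23	0	4	-	+	-	-	-	++	++
miR167	mno-miR167h	mdm-miR167h	TGAAGCTGCCAGCATGATCTTA	22	1410	18	881	-	+	++	+	+	-	+
miR167	mno-miR167b	bna-miR167b	TGAAGCTGCCAGCATGATCTAA	22	574	84	1526	+	+	+	+	+	+	+
miR167	mno-miR167c	nta-miR167c	TGAAGCTGCCAGCATGATCTGG	22	115	125	28	++	+	+	+	++	+	+
miR167	mno-miR167a	ath-miR167a	TGAAGCTGCCAGCATGATCTA	21	75303	12129	140989	++	++	++	++	++	++	++
miR167	mno-miR167d	cme-miR167c	TGAAGCTGCCAGCATGATCTT	21	3722	324	4334	-	++	++	++	+	-	+
miR167	mno-miR167e	cme-miR167f	TGAAGCTGCCAGCATGATCTG	21	47	21	43	++	++	+	++	++	++	++
miR168	mno-miR168a	aau-miR168	GATCCCGCCTTGCATCAACTGAAT	24	9	27	12	-	-	-	+	-	+	-
miR168	mno-miR168b	mdm-miR168b	TCGCTTGGTGCAGGTCGGGAA	21	18898	33236	31342	++	++	++	++	++	+	+
miR168	mno-miR168c	mtr-miR168c-3p	CCCGCCTTGCATCAACTGAAT	21	246	891	476	-	-	-	++	-	-	+
miR169	mno-miR169a	cme-miR169f	CAGCCAAGGATGACTTGCCGG	21	113	386	1314	++	++	++	++	++	++	++
miR169	mno-miR169c	nta-miR169p	CAGCCAAGGATGACTTGCCGA	21	73	0	106	++	++	+	++	+	++	++
miR169	mno-miR169b	zma-miR169b-3p	GGCAAGTTGTTCTTGGCTACA	21	1	0	0	-	+	-	+	-	-	++
miR171	mno-miR171a	cme-miR171f	TGATTGAGCCGTGCCAATATC	21	379	5	528	+	++	++	++	++	++	++
miR171	mno-miR171d	mdm-miR171l	TTGAGCCGCGCCAATATCACT	21	36	9	3	+	++	++	+	+	+	+
miR171	mno-miR171b	gma-miR171b-3p	CGAGCCGAATCAATATCACTC	21	34	603	127	-	++	+	+	+	+	+
miR171	mno-miR171e	mdm-miR171n	TTGAGCCGTGCCAATATCACA	21	32	1	0	+	++	++	+	+	-	++
miR171	mno-miR171c	ptc-miR171c	AGATTGAGCCGCGCCAATATC	21	29	75	27	+	+	+	++	++	+	+
miR171	mno-miR171f	gma-miR171j-5p	TATTGGCCTGGTTCACTCAGA	21	6	0	2	-	++	-	-	-	+	+
miR171	mno-miR171g	mdm-miR171b	TTGAGCCGCGTCAATATCTCC	21	5	600	8	-	+	++	-	-	+	+
miR171	mno-miR171h	cme-miR171b	TTGAGCCGTGCCAATATCACG	21	4	0	5	++	++	++	++	++	-	+
miR171	mno-miR171i	gma-miR171l	CGATGTTGGTGAGGTTCAATC	21	2	0	0	-	++	-	-	-	+	-
miR172	mno-miR172a	cme-miR172c	AGAATCTTGATGATGCTGCAT	21	19265	8484	1245	++	++	++	++	-	++	+
miR172	mno-miR172b	cme-miR172e	AGAATCTTGATGATGCTGCAG	21	143	13	137	++	+	++	+	+	+	+
miR172	mno-miR172c	cme-miR172d	GGAATCTTGATGATGCTGCAT	21	15	266	6	++	++	++	++	+	++	++
miR172	mno-miR172d	aly-miR172c-5p	GGAGCATCATCAAGATTCACA	21	11	6	4	-	+	-	++	-	+	+
miR172	mno-miR172e	tcc-miR172d	AGAATCCTGATGATGCTGCAT	21	3	2	0	+	+	+	+	-	+	+
miR172	mno-miR172f	mtr-miR172c-5p	GTAGCATCATCAAGATTCACA	21	1	6	0	-	+	-	+	-	+	+
miR319	mno-miR319a	tcc-miR319	TTTGGACTGAAGGGAGCTCCT	21	2	0	9	+	+	+	+	+	+	+
miR319	mno-miR319b	mdm-miR319b	TTGGACTGAAGGGAGCTCCCT	21	0	57	0	++	++	++	+	++	+	+
miR319	mno-miR319c	ppt-miR319e	CTTGGACTGAAGGGAGCTCCC	21	0	4	0	+	+	+	+	+	+	+
miR390	mno-miR390	cme-miR390c	AAGCTCAGGAGGGATAGCGCC	21	4275	489	1153	++	++	++	++	++	++	++
miR393	mno-miR393a	aly-miR393a-3p	ATCATGCTATCTCTTTGGATT	21	36	25	37	-	-	-	+	-	-	-
miR393	mno-miR393b	cme-miR393c	TCCAAAGGGATCGCATTGATC	21	2	4	2	++	++	++	++	++	++	++
miR393	mno-miR393c	mdm-miR393c	TCCAAAGGGATCGCATTGATCT	22	0	103	19	+	+	++	+	+	++	++
miR395	mno-miR395a	cca-miR395c	CTGAAGTGTTTGGAGGAACTC	21	0	2	0	+	+	+	+	+	+	+
miR395	mno-miR395b	cme-miR395f	CTGAAGTGTTTGGGGGAACTC	21	43	104	47	++	++	++	++	++	+	+
miR396	mno-miR396a	gma-miR396k	GCTCAAGAAAGCTGTGGGAGA	21	848	149	135	-	++	-	+	-	+	+
miR396	mno-miR396b	cme-miR396b	TTCCACAGCTTTCTTGAACTG	21	190	2750	657	++	++	++	++	+	++	++
miR396	mno-miR396c	cme-miR396d	TTCCACAGCTTTCTTGAACTT	21	181	57	105	++	++	++	++	++	++	++
miR396	mno-miR396d	gma-miR396i-3p	GTTCAATAAAGCTGTGGGAAG	21	12	128	47	-	++	-	-	-	+	+
miR397	mno-miR397a	cme-miR397	TCATTGAGTGCAGCGTTGATG	21	211	154	1483	++	++	+	++	++	++	+
miR397	mno-miR397b	osa-miR397b	TTATTGAGTGCAGCGTTGATG	21	0	1	0	+	+	+	+	+	++	+
miR398	mno-miR398	cme-miR398a	TGTGTTCTCAGGTCGCCCCTG	21	130	32	332	+	++	++	++	++	++	+
miR399	mno-miR399a	mdm-miR399c	TGCCAAAGGAGAATTGCCCTG	21	179	3	0	+	+	++	++	+	++	++
miR399	mno-miR399b	mdm-miR399j	TGCCAAAGGAGAGTTGCCCTG	21	111	1	83	++	++	++	+	++	++	++
miR399	mno-miR399c	zma-miR399e-5p	GGGCTTCTCTTTCTTGGCAGG	21	36	0	16	-	-	-	-	-	-	++
miR399	mno-miR399d	gma-miR399g	TGCCAAAGGAGATTTGCCCAG	21	26	4	71	+	++	+	+	++	++	+
miR399	mno-miR399e	cme-miR399a	TGCCAAAGGAGATTTGCCCCG	21	11	0	0	++	+	+	++	+	+	+
miR399	mno-miR399f	cme-miR399c	TGCCAAAGGAGATTTGCCCGG	21	9	2	28	++	+	+	++	++	+	+
miR408	mno-miR408a	nta-miR408	TGCACTGCCTCTTCCCTGGCT	21	0	0	2	+	+	+	+	+	+	+
miR408	mno-miR408b	smo-miR408	TGCACTGCCTCTTCCCTGGCTG	22	2	0	6	+	+	+	+	+	+	+
miR408	mno-miR408c	cme-miR408	ATGCACTGCCTCTTCCCTGGC	21	219	59	838	++	++	++	++	+	+	+
miR482	mno-miR482	mdm-miR482a-5p	AGGAATGGGCTGTTTGGGAAGA	22	23	54	25	-	-	++	-	-	-	-
miR529	mno-miR529a	osa-miR529b	AGAAGAGAGAGAGTACAGCTT	21	2851	367	6790	-	-	-	-	-	++	+
miR529	mno-miR529b	far-miR529	AGAAGAGAGAGAGCACAGCTT	21	3	0	5	-	-	-	-	-	+	+
miR535	mno-miR535	mdm-miR535a	TGACAACGAGAGAGAGCACGC	21	21566	57272	19329	-	-	++	-	++	++	-
miR827	mno-miR827	mdm-miR827	TTAGATGACCATCAACGAACA	21	2	0	0	+	-	++	+	-	+	+
miR828	mno-miR828	cme-miR828	TCTTGCTCAAATGAGTATTCCA	22	5	1	0	+	++	++	++	-	-	-
miR858	mno-miR858	ath-miR858b	TTCGTTGTCTGTTCGACCTTG	21	17	17	2	++	-	+	-	-	-	-
miR2111	mno-miR2111	cme-miR2111b	TAATCTGCATCCTGAGGTTTA	21	11	10	10	++	++	++	+	-	-	-
miR4376	mno-miR4376	gma-miR4376-5p	TACGCAGGAGAGATGACGCTGT	22	9535	1231	6682	-	++	+	-	-	-	-
miR4414	mno-miR4414	mtr-miR4414a-5p	AGCTGCTGACTCGTTGGTTCA	21	121	92	6	-	+	-	-	-	-	-
miR4995	mno-miR4995	gma-miR4995	AGGCAGTGGCTTGGTTAAGGG	21	10	0	0	-	++	-	-	-	-	-
miR5523	mno-miR5523	osa-miR5523	TGAGGAGGAACATATTTACTAG	22	0	1	2	-	-	-	-	-	++	-
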