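name	query_mirna	mature_len	mature_seq	n_mismatches	arm	gc_percent	precursor_len	mfe_abs	mfei	source_read
pgi-miR1128	ssp-miR1128	21	UGCUACUCCCUCCGUCCCAAA	5	5p	22	290	99.2	1.55	G8WERZI02JSLMP
pgi-miR827	tcc-miR827	21	UUAGAUGAUCAUCAGCAAACA	1	3p	32	117	43.2	1.15	G8WERZI01D2S8J
pgi-miR1439	osa-miR1439	21	UUUUGGAACGGAGGGAGUAUU	4	3p	28	294	92.6	1.12	G8WERZI01A17SA
pgi-miR5658	ath-miR5658	21	AUGAUGAUGAUGAUGAUGAGG	3	3p	39	80	34.7	1.11	G9IMXQ301ESZFB
pgi-miR396i-3p	gma-miR396i-3p	21	GUUCAAUAAAGCUGUGGGAAG	1	3p	43	119	54.6	1.07	G9IMXQ302GOGE4
pgi-miR390b	bdi-miR390b	21	AAGCUCAGGAGGGAUAGCGCC	1	5p	39	175	72.5	1.06	G9IMXQ302H2ZM1
pgi-miR5021	ath-miR5021	20	GAAGAAGAAGAAGAAGAAAA	3	5p	32	134	44.8	1.04	G9IMXQ301DYCTK
pgi-miR156b	vun-miR156b	21	UGACAGAAGACUAGAGAGCAC	1	5p	44	112	49.6	1.01	G9IMXQ302IGRXR
pgi-miR403b	tcc-miR403b	21	UUAGAUUCACGCACAAACUCG	3	3p	41	117	46.8	0.98	G9IMXQ301CU7GZ
pgi-miR172	aau-miR172	22	UGAGAAUCUUGAUGAUGCUGCA	3	3p	44	171	71	0.94	G9IMXQ301B4R7M
pgi-miR408	vun-miR408	21	AUGCACUGCCUCUUCCCUGGC	4	3p	50	115	53.6	0.93	G9IMXQ301BH247
pgi-miR399d	tcc-miR399d	21	UGCCAAAGGAGAUUUGCCCGG	3	3p	41	122	45.2	0.9	G8WERZI01A00R5
pgi-miR482	gra-miR482	22	UCUUGCCAAUUCCUCCCAUUCC	3	3p	43	97	37.2	0.89	G9IMXQ301C4CDG
pgi-miR3441.1	aly-miR3441.1	20	UUCAAAGCCUCUUUGAAGGA	5	3p	38	68	21.9	0.85	G9IMXQ301DXOD1
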