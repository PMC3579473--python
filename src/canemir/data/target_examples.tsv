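# Worked miRNA:target alignment examples for drought-modulated sugarcane miRNAs,
# with the expectation score reported for each site and the aligned fragments as
# printed (both 5'->3').  clean=1 marks rows whose fragments are internally
# consistent and reproduced exactly by the default penalty scheme
# (match 0, G:U 0.5, mismatch 1); clean=0 rows carry apparent typesetting
# errors (length-inconsistent or penalty-inconsistent fragments) and are kept
# for reference only.
mirna	target_acc	expectation	upe	target_start	target_end	mirna_fragment	target_fragment	clean
ssp-miR160-seq1	SCCCLR1C04H01.g	2.5	24.709	1087	1106	UGCCUGGCUCCCUGUAUGCC	GGCAGGCAGGCAGCCAGGCA	1
ssp-miR166-seq3	SCRFLR1034E12.g	3.0	22.151	875	894	UCGGACCAGGCUUCAAUCCCU	GGGAUGAAGCCUGGUCCGG	0
ssp-miR169-seq2	SCACST3157E03.g	2.5	16.856	121	141	CGGCAAGUUGUUCUUGGCUAC	GCAGCCAAGAAUGAUUUGCCU	0
ssp-miR171-seq2	SCJFAD1013C10.g	0.5	23.909	574	594	UGAUUGAGCCGUGCCAAUAUC	GAUAUUGGCGCGGCUCAAUCA	1
ssp-miR172	SCJLRT1022F08.g	2.5	15.83	632	651	AGAAUCUUGAUGAUGCUGCAU	GCAGCAUCAUCACGAUUCC	0
ssp-miR393	TC120009	1.0	20.653	302	320	CUCCAAAGGGAUCGCAUUG	CAAUGCGAUCCCUUUGGAU	1
ssp-miR394	SCUTLR1037A06.g	3.0	22.853	1222	1240	UUGGCAUUCUGUCCACCUC	GAGGUGGUCAGGAUGCUGG	1
ssp-miR399-seq3	SCJFLR1017A12.g	2.5	18.233	290	308	GUGCAGCUCUCCUCUGGCA	GGCCAGAAGGGAGCUGCAC	1
ssp-miR528	SCCCCL1002D10.b	2.5	10.325	133	153	UGGAAGGGGCAUGCAGAGGAG	UUCCUCCGCACGCCCUUUCCA	0
ssp-miR1432	SCSFFL4085D03.g	3.0	15.088	624	642	UCAGGAAAGAUGACACCAA	UUGGUGUUUUCUUCCCUGA	0
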