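event_id	responder_phbr	responder_best_peptide_hla	nonresponder_phbr	gene_symbol	premature_stop	stronger_in_responders
chr1:84563245-84563256	0.04	YYNYKVRLF HLA-C07:51	0.04	CTBS	0	0
chr4:4237071-4237077	0.05	HPILRSAAL HLA-B35:03	0.06	TMEM128	0	0
chr7:75881487-75881490	0.3	LPSEVVYRL HLA-B35:01	0.4	RHBDD2	0	0
chr5:74700753-74700851	0.44	SLQPPPLRFK HLA-A03:01	1.57	HEXB	0	1
chr20:6006807-6006834	0.47	IKYENPWTI HLA-C06:02	0.49	CRLS1	0	0
chr2:37317807-37317899	0.56	RTWIGEIPY HLA-A32:01	1.99	PRKD3	0	0
chr2:11450008-11450011	0.58	VPAPREVGL HLA-B07:02	2.18	E2F6	0	1
chr1:112669896-112669918	1	NEYQGTQAY HLA-B44:03	0.77	CAPZA1	0	0
chr22:50204986-50205024	1.03	RQILGDPTY HLA-B15:01	9.15	SELENOO	0	1
chr7:72901070-72901128	1.09	NPPTTVSQI HLA-B51:01	0.69	POM121	0	0
chr1:236207133-236207172	1.17	STEEKLGEY HLA-A01:01	0.96	GPR137B	0	0
chr22:31176262-31176358	1.17	SPVSDSQLL HLA-B35:03	0.75	RNF185	0	0
chr9:33338507-33338509	1.24	SLKSEADATF HLA-B15:01	1.72	NFX1	0	0
chr2:144229849-144229871	1.3	LFYRGSLYL HLA-A23:01	9.09	GTDC1	0	1
chr11:86318936-86318960	1.35	GLKSETGSY HLA-B15:01	0.89	HIKESHI	0	0
chr22:43074660-43074673	1.67	QSLPMLPRL HLA-B57:01	NA	TTLL1	1	0
chr2:39254521-39254545	1.68	IESIVIELF HLA-B44:02	0.79	MAP4K3	0	0
chr10:91997080-91997108	1.73	KRWMKIKSV HLA-C06:02	1.14	BTAF1	0	0
chr7:6257736-6257769	1.82	AAVPEDLSL HLA-C03:04	1.19	CYTH3	0	0
chr8:97696204-97696221	1.85	SIFSGIAAW HLA-A32:01	3.12	MTDH	0	1
chr5:17143578-17143591	2.27	EEANTCSFW HLA-B44:02	2.53	BASP1	0	0
chr13:95816081-95816104	2.34	KIQALQEAW HLA-A32:01	2.6	UGGT2	0	0
chr6:35352929-35353001	2.58	NTKRRDSL HLA-B08:01	6.43	PPARD	0	0
chr20:62843780-62843793	3.2	RFRETESGLEF HLA-A24:02	5.25	TCFL5	0	0
chr3:47940517-47940534	3.39	GSDTTGESKSL HLA-C08:02	3.41	MAP4	0	0
chr6:96897659-96897665	3.7	REQISRECL HLA-B40:01	2.24	NDUFAF4	0	0
chr7:104740892-104740916	4.95	SRDQLGNMV HLA-B39:01	1.72	LHFPL3	0	0
chr1:185091565-185091578	5.31	QEAITDGLEI HLA-B40:01	9.98	RNF2	0	0
chr7:150408642-150408664	23.61	ELKETWRGHF HLA-B08:01	35.71	LOC728743	0	0
chr20:348046-348063	30.87	RGSGELEGR HLA-A31:01	24.59	NRSN2	0	0
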