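event_id	ase_phbr	wt_phbr	best_peptide_hla	pct_samples	gene_symbol	pct_outlier_oe	no_binding_wt
chr19:2037829-2040134	0.38	3.12	QRWDSHFLL B27:05	100	MKNK2b	61.7	1
chr9:136792030-136792251	0.43	0.44	VVAGSVVSY A26:08	100	TMEM141	57.4	0
chr6:167010893-167013508	0.45	4.21	TTPSKIPRY A26:08	97.9	FGFR1OP	78.7	1
chr6:167003811-167004264	0.55	3.87	VFQPETSTL C14:02	100	FGFR1OP	83	1
chr9:4727924-4740937	0.61	1.34	ASLFPETQQY B15:01	66	AK3	40.4	0
chr16:29996617-29996808	0.7	4.09	SFLLDRLLQY A29:02	100	INO80E	44.7	1
chr14:105491522-105491622	0.74	1.12	RPEATSAL B07:02	91.5	C14orf80	59.6	0
chr3:158649157-158650005	0.79	1.34	YFDGDFGHF C04:01	61.7	GFM1	31.9	0
chr17:28399713-28400610	1.15	4.13	AVLIGMLEK A11:01	91.5	SLC46A1	48.9	1
chr2:130359492-130359608	1.21	2.44	WEFGVKVIL B40:01	89.4	PTPN18	51.1	1
chr9:34665680-34665978	1.33	3.09	SQPPLQETF B15:01	59.6	LOC730098	55.3	1
chr7:44208198-44211023	1.35	3.54	LHNTMESLL B38:01	97.9	YKT6	48.9	1
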