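gene_ids	homologues	product	fold_change_T30_glnR	sites
Sven_1863	SCO2198	GSI	-1.2	TTAACTTCGACGAAAC;GTCATGCTTGAGAAAT
Sven_1874	SCO2210	GSII	-291.6	GTAACACGGGGTTCAC;GCAACCGACGGGAAAT
Sven_7046	n/a	NRPS cluster	1.1	GAAACACGGGCGAAAC
Sven_5517	SCO5842	Putative acetyltransferase	1.4	n/a
Sven_6731	SCO5931	Xylanase	-1.5	GAAACATCTTCGAAAC
Sven_5279	SCO5583	AmtB	-624.7	GTCACGGCTCCGAAAC;TTCACGGTCGCGTAAC
Sven_4770	n/a	Unknown	-1.1	TTAACGCGCAGGCAAC
Sven_3917/Sven_3918	SCO4159/SCO4160	GlnR/putative hydrolase	n/a/30.7	TTCATCCATCCGTAAC
Sven_6152/Sven_6153	n/a	ATP-cassette/cytochrome P450	1.0/-1.2	GTTACCCCCACGTAAC;GTTACCGTCGGGTCAC;GTAACCGGTCGGTAAG;GTGACCCGACGGTAAC
Sven_6199/Sven_6200	n/a	NRPS cluster	1.7/3.2	TTCACTCCGGCGAAAC;GTGACCGCTGAGTAGC;TTGATCTCCTGGTAAA
Sven_2720	SCO2958	Fused RR/uroporphrinogen III synthase	-13.7	n/a
Sven_2830	n/a	beta-glucan synthesis	-1.4	n/a
Sven_0629/Sven_0630	SCO6598/SCO0545	LacI family repressor/secreted protein	2.5/1.5	GATACAGGGGGGAAAC
Sven_0867	SCO1293	N-acetyl glutamate synthase	-9.1	TTAACCCGTCAGTCAC
Sven_1634	SCO2008	Branched chain amino acid binding protein	-1.3	ATAACAAGACAGTCAC
Sven_1677	SCO2026	Glutamate synthase	-1.1	GTAACCTGCACGAAAT
Sven_5967	SCO3051	FadE acetyl CoA dehydrogenase	-1.3	GACACCCCGAGTTAAC
Sven_6632	SCO5685	Putative sugar hydrolase	1.4	GTTAAGTGAACGTCAC
Sven_0035	-	Secreted protein	-1.2	GTGACGCCGAGGTTAC
Sven_2895	SCO3092	Fragment of NADH dehydrogenase	1.0	TTCACAAGGGGTGAAC
Sven_2285	SCO4892	Transcriptional regulator	1.1	GAAACACCCTGGTAAC
Sven_6163	n/a	Unknown	-1.6	n/a
Sven_2694	SCO2937	Transcriptional regulator	-1.4	n/a
Sven_0835	SCO1236	UreA	-2.5	TTAACGAGCCGGAAAA
Sven_1338/Sven_1339	SCO1721/n/a	Probable serine/threonine protein kinase	1.6/-1.4	GATACACGGGTGTCAC
Sven_1860	SCO2195	Unknown	-4.5	GTCACGCCCTGGTAAC
Sven_6307	SCO6473	Crotonyl-CoA reductase	-1.7	n/a
Sven_5972/Sven_5973	n/a	JadR2/JadR1 (and small orf inbetween)	1.1/-1.7	TTAATGGCGGCGTCAC;TTGACCACTTCTTGAC;TTGACACGGAGTTGAC;GTCAACTCCGTGTCAA
Sven_0812	SCO2423	Secreted protein	1.3	GTTTCCCGCAAGTAAC
Sven_1894/Sven_1895	SCO2231/SCO2232	Maltose binding protein/transcriptional repressor	1.1/1.2	GACACGCGGATGTAAC
Sven_3785	SCO4034	RNA polymerase sigma factor N	-1.0	n/a
Sven_4759	n/a	Putative peptide transport system secreted peptide-binding protein	1.6	n/a
Sven_1354	SCO1735	Probable secreted lipase	1.3	TTTACCGACGCGTAAC;GTCACGCCTTCATGAC
Sven_6299/Sven_6300	n/a/SCO6803	Epimerase/acetyl transferase	1.9/-6.1	TTCACGTGCCCGAAAC
Sven_7354	SCO7012	Putative binding protein dependent transport protein permease	-3.7	n/a
Sven_7089	n/a	Assimilatory nitrate reductase	-1.8	GTGACACAGGTGTAAC
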