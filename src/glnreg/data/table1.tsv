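gene_id	homologue	product	fold_induction	fold_repression
Sven_5279	SCO5583	ammonium transporter amtB	76.4	15.0
Sven_5281	SCO5585	PII uridylyltransferase glnD	26.0	8.3
Sven_2720	SCO2958	putative transcriptional regulator	21.6	6.0
Sven_5280	SCO5584	nitrogen regulatory protein PII glnK	16.0	6.8
Sven_2606	SCO2816	conserved hypothetical protein	15.4	3.9
Sven_0745	SCO1118	putative integral membrane protein	13.6	9.9
Sven_4809	SCO5163	unknown	12.5	3.7
Sven_0933	-	putative cholesterol esterase	11.7	7.2
Sven_6300	SCO6803	putative acetyltransferase	9.8	2.9
Sven_4564	SCO4896	putative transport integral membrane protein	9.2	7.3
Sven_1595	SCO1963	putative integral membrane export protein	8.7	2.2
Sven_3456	SCO6809	putative integral membrane transport protein	7.9	6.2
Sven_1523	-	unknown	7.7	4.5
Sven_2474	SCO5348	putative excisionase	7.4	2.7
Sven_3334	SCO3564	putative Na+/H+ antiporter	7.3	4.6
Sven_0739	SCO1109	putative oxidoreductase	7.2	4.4
Sven_3030	SCO3185	putative Na+/H+ antiporter	7.1	4.1
Sven_0867	SCO1293	putative acetyltransferase	6.7	5.2
Sven_1874	SCO2210	glutamine synthetase II glnII	6.5	3.6
Sven_3001	SCO3167	putative TetR-family transcriptional regulator	6.4	7.5
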