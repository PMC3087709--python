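gene_id	homologue	product
Sven_5279	SCO5583	ammonium transporter, amtB
Sven_5281	SCO5585	PII uridylyltransferase, glnD
Sven_2720	SCO2958	putative transcriptional regulator
Sven_2606	SCO2816	conserved hypothetical protein
Sven_6300	SCO6803	putative acetyltransferase
Sven_4564	SCO4896	putative integral membrane protein
Sven_1595	SCO1963	putative integral membrane export protein
Sven_2474	SCO5348	putative excisionase
Sven_3334	SCO3564	putative Na+/H+ antiporter
Sven_0867	SCO1293	c-terminal homology to acetyltransferase
Sven_1874	SCO2210	glutamine synthetase II glnII
Sven_5427	SCO5772	putative cysteine dioxygenase
Sven_1172	SCO1578	acetylglutamate kinase
Sven_3383	-	putative PIN domain containing protein
Sven_0779	-	putative permease
Sven_6135	-	putative major facilitator super family transporter
Sven_2419	SCO2636	unknown
Sven_1169	SCO1572	putative secreted protein
Sven_4152	SCO4337	putative integral membrane efflux protein
Sven_1173	SCO1579	putative glutamate N-acetyltransferase
Sven_2176	SCO2362	unknown
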