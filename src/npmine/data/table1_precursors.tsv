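name	family_label	family	contigs	transcript_length_bp	reference_accession	race5	race3	evalue	score	genbank_accession
BnVP-like	Arginine-vasotocine	vasopressin	BN_contig_97286,BN_contig_87480	599	AAX18227.1	+	+	4.00E-09	61.2	KX095876
BnPEP-like	Pedal peptide/orcokinin neuropeptide	pedal_orcokinin_FDSIG	BN_contig_141741,BN_contig_166562,BN_contig_98929	792	AHB62384.1	+	-	1.00E-05	55.1	KX095877
BnFDSIG-like	Pedal peptide/orcokinin neuropeptide	pedal_orcokinin_FDSIG	BN_contig_220841,BN_contig_55496	697	AEE25644.1	+	+	1.00E-10	72	KX095878
BnNPF-like	Neuropeptide Y	NPF	BN_contig_222301,BN_contig_184693	476	AGM46557.1	+	+	8.00E-10	61.6	KX095879
BnGHB	Glycoprotein hormone-beta5-I	GPB5	BN_contig_4814	949	CAR95348.2	+	+	6.00E-08	57.4	KX095880
BnILP-A	Insulin-like peptide	insulin_like	BN_contig_62648,BN_contig_127297	1220	XP_008642491.1	+	+	3.00E-27	112	KX095882
BnINS_B	Insulin-like peptide	insulin_like	BN_contig_36942	371	Q9W7R2.1	-	-	4.00E-25	44.3	KX095885
BnINS_C	Insulin-like peptide	insulin_like	BN_contig_203950	675	CAC20109.1	+	+	3.00E-04	59.7	KX095886
BnILP-D	Insulin-like peptide	insulin_like	BN_contig_236733	1029	XP_011415724.1	+	+	5.00E-08	59.3	KX095881
BnILP-E	Insulin-like peptide	insulin_like	BN_contig_208700,BN_contig_236692	696	XP_012388351.1	+	-	1.00E-11	69.3	KX095883
BnILP-F	Insulin-like peptide	insulin_like	BN_contig_8730	547	ABB23272.1	-	+	5.00E-17	83.6	KX095884
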