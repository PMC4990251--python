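precursor	table1_name	variant	printed_sequence
BnFDSIG-like	BnFDSIG-like	P1	SFDSIGNGPIGLKR
BnFDSIG-like	BnFDSIG-like	P2	SFDGIGNGPIGLKR
BnFDSIG-like	BnFDSIG-like	P3	SRDSIGFGPIGLKR
BnFDSIG-like	BnFDSIG-like	P4	SFGGIGGRPASYKR
BnPep-like	BnPEP-like	P1	YLERIGSGNALISKR
BnPep-like	BnPEP-like	P2	YLERIGSGNSVIKK
BnPep-like	BnPEP-like	P3	QHLKGSGENSLPKKR
BnPep-like	BnPEP-like	P4	YLERIGSGNELVGKR
BnPep-like	BnPEP-like	P5-partial	YLERIGSGND
BnVP-like	BnVP-like	Vasopressin-like	CYIRTCDLGILGKR
BnVP-like	BnVP-like	Neurophysin	TVEGKPALCRACGPGLAGQCYGNSYCCGYFGCYNVRKTDECQISSPTQSRLCKKGFSPCFTIPGGSCSANGFCCNSDTCRPSLTCVRLTNLYGEPEKHHRV
BnGHB5	BnGHB		TPVPFPASGCNLITVRLNVTNGANSHCWGLIDFSGCGGYCESYDIILPEPPYRDRHHQVCGFADYEHVETILANCHQGYSPEVFKFPKVTSCSCRECDPMREVCM
BnNPFL	BnNPF-like		GPPEPQSKFKSPEELKQYLKSLEEY(SOH)LAY(SOH)NDPVRFGKR
BnILP-A	BnILP-A	ChainB	DFEHMCVHEDFSRSGAYSSCGSRLTSLVISKCDGNPYLASRGKR
BnILP-A	BnILP-A	ChainC	DLEKISLTTESANSYLRPKR
BnILP-A	BnILP-A	ChainA	NYEYVEDGMGVGIICECCVNTCTIRELDQYCESKR
BnILP-B	BnINS_B	ChainB	GTSAEEYKVCTIKDSPNPRGMCGSQVFKQIYVICNGNIYSSGFLTSPDRR
BnILP-B	BnINS_B	ChainC	AIRPHVSDISSNRNTANSFLSQSKR
BnILP-B	BnINS_B	ChainA	QFEFLEDERDARMMGIHCECCIHTCTLEEKQEYCGSKR
BnILP-C	BnINS_C	ChainB	TFSAAELTHTCTYERLTSGYHGRMSRCGGELTDYVLSKCYGYQPYRRRR
BnILP-C	BnINS_C	ChainC	AVSTLLNNTPDKQVIKQQETTEANSVFKSHSKANEFLFRQKR
BnILP-C	BnINS_C	ChainA	QHGGFIPSNSQGIVCECCVYGCNDNEIMQYCEEFKR
BnILP-D	BnILP-D	ChainB	LERICHMDDQSNKDPGLCRRRLQLYLSRICNGDITPIK
BnILP-D	BnILP-D	ChainC	HNHITEQLSESEQNPTTANPISGISSSRETANAFLNHSKR
BnILP-D	BnILP-D	ChainA	QQAESDDVNTFSGIICECCFHPCSEYELSEYCGSKRRRKR
BnILP-E	BnILP-E	ChainB	DFEHTCQTDVQSPYTFCGQILTNMVFDKCGDER
BnILP-E	BnILP-E	ChainC	LSQLAVLDVGVTASITHDIFISAKK
BnILP-E	BnILP-E	ChainA	ANSLLMFSAGLNAESGIYCECCVNRCTVTELEQYCNPLAAIQPRLRR
BnILP-F	BnILP-F	ChainB-partial	PYINKR
BnILP-F	BnILP-F	ChainC	AFDDDSKNQPRVSQNIFVSKNHSNEFLNPKR
BnILP-F	BnILP-F	ChainA	NGHERSQYGVVCECCINPCTLREMQAYCAKKR
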