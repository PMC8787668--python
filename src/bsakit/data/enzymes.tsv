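name	recognition	cut_offset
DdeI	CTNAG	1
EcoRI	GAATTC	1
HindIII	AAGCTT	1
BamHI	GGATCC	1
TaqI	TCGA	1
MseI	TTAA	1
AluI	AGCT	2
DraI	TTTAAA	3
HaeIII	GGCC	2
RsaI	GTAC	2
HinfI	GANTC	1
Sau3AI	GATC	0
PstI	CTGCAG	5
SmaI	CCCGGG	3
HpaII	CCGG	1
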