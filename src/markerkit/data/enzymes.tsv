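# name	recognition	cut_offset (top-strand cut position within the site)
AluI	AGCT	2
ApaI	GGGCCC	5
BamHI	GGATCC	1
BbrPI	CACGTG	3
BfrI	CTTAAG	1
ClaI	ATCGAT	2
DdeI	CTNAG	1
DpnII	GATC	0
DraI	TTTAAA	3
EcoRI	GAATTC	1
HaeIII	GGCC	2
HincII	GTYRAC	3
HinfI	GANTC	1
HpaI	GTTAAC	3
PvuII	CAGCTG	3
RsaI	GTAC	2
SacI	GAGCTC	5
Sau3AI	GATC	0
SmaI	CCCGGG	3
TaqI	TCGA	1
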