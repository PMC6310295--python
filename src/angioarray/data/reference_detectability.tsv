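protein	BL	SOM	EOT
Activin A	18	14	14
ADAMTS-1	ND	5	5
Amphiregulin	14	5	18
Angiogenin	100	100	100
Angiopoietin-1	95	100	95
Angiopoietin-2	9	5	9
Angiostatin	95	95	95
Artemin	9	5	5
Coagulation Factor III	14	9	18
CXCL16	100	95	95
DPPIV	100	100	95
EG-VEGF	10	5	9
EGF	71	18	36
Endoglin	100	100	95
Endostatin	100	95	95
Endothelin-1	81	68	82
FGF acidic	5	ND	5
FGF basic	ND	ND	ND
FGF-4	5	5	ND
FGF-7	ND	ND	ND
GDNF	ND	ND	ND
GM-CSF	5	9	9
HB-EGF	64	59	50
HGF	77	55	73
IGFBP-1	100	100	100
IGFBP-2	100	100	100
IGFBP-3	95	95	95
IL-1β	9	ND	5
IL-8	14	5	9
LAP/TGF-β1	23	18	18
Leptin	91	100	100
MCP-1	ND	ND	ND
MIP-1α	ND	ND	ND
MMP-8	100	100	100
MMP-9	95	95	95
NRG1-β1	9	5	5
PD-ECGF	23	23	23
PDGF-AA	100	100	100
PDGF-AB/PDGF-BB	91	86	86
Pentraxin 3 (PTX3)	100	100	100
Persephin	14	9	9
Platelet Factor 4	95	95	91
PlGF	14	18	18
Prolactin	100	100	100
Serpin B5	ND	ND	ND
Serpin E1	95	95	95
Serpin F1	32	32	27
Thrombospondin-1	77	86	86
Thrombospondin-2	23	14	14
TIMP-1	100	100	100
TIMP-4	100	100	100
uPA	91	91	86
Vasohibin	ND	ND	ND
VEGF	91	100	95
VEGF-C	ND	ND	ND
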