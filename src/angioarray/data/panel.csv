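name,aliases,index
Activin A,,1
ADAMTS-1,,2
Amphiregulin,AR;AREG,3
Angiogenin,ANG;ribonuclease 5,4
Angiopoietin-1,Ang-1,5
Angiopoietin-2,Ang-2,6
Angiostatin,Plasminogen,7
Artemin,Enovin;Neublastin,8
Coagulation Factor III,TF;tissue factor;thromboplastin;CD142,9
CXCL16,,10
DPPIV,CD26;CD 26,11
EG-VEGF,PK1,12
EGF,epidermal growth factor,13
Endoglin,CD105,14
Endostatin,Collagen XVIII,15
Endothelin-1,ET-1,16
FGF acidic,FGF-1,17
FGF basic,FGF-2;FGF-b,18
FGF-4,,19
FGF-7,KGF;keratinocyte growth factor,20
GDNF,,21
GM-CSF,,22
HB-EGF,Hb-EGF,23
HGF,Hepatopoietin A;scatter factor,24
IGFBP-1,,25
IGFBP-2,,26
IGFBP-3,,27
IL-1β,IL-1b;IL-1beta;IL-1F2,28
IL-8,CXCL8,29
LAP/TGF-β1,LAP/TGF-b1;latency associated peptide,30
Leptin,,31
MCP-1,CCL2,32
MIP-1α,MIP-1a;CCL3,33
MMP-8,,34
MMP-9,Gelatinase B,35
NRG1-β1,NRG1-b1;HRG1-b1,36
PD-ECGF,TYMP,37
PDGF-AA,PDGF-aa,38
PDGF-AB/PDGF-BB,PDGF-ab;PDGF-AB;PDGF-BB,39
Pentraxin 3 (PTX3),PTX3;PTX-3;TSG-14,40
Persephin,,41
Platelet Factor 4,PF4;PF-4;CXCL4,42
PlGF,placenta growth factor,43
Prolactin,,44
Serpin B5,Maspin,45
Serpin E1,PAI-1,46
Serpin F1,PEDF,47
Thrombospondin-1,TSP-1,48
Thrombospondin-2,TSP-2,49
TIMP-1,,50
TIMP-4,,51
uPA,urokinase-type plasminogen activator,52
Vasohibin,,53
VEGF,VEGF-A,54
VEGF-C,,55
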