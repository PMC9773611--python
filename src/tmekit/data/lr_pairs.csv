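ligand,receptor,annotation
WNT5A,MCAM,WNT non-canonical
WNT5A,FZD5,WNT non-canonical
WNT5A,ROR2,WNT non-canonical
WNT2,FZD4,WNT canonical
WNT2B,FZD4,WNT canonical
LRP1,SERPINE1,protease regulation
TSLP,IL7R,cytokine
IL7,IL7R,cytokine
XCL1,XCR1,chemokine
XCL2,XCR1,chemokine
CXCL1,CXCR1,chemokine
CXCL1,CXCR2,chemokine
CXCL2,CXCR2,chemokine
CXCL3,CXCR2,chemokine
CXCL5,CXCR2,chemokine
CXCL8,CXCR1,chemokine
CXCL8,CXCR2,chemokine
CXCL9,CXCR3,chemokine
CXCL10,CXCR3,chemokine
CXCL11,CXCR3,chemokine
CXCL12,CXCR4,chemokine
CXCL13,CXCR5,chemokine
CXCL16,CXCR6,chemokine
CCL2,CCR2,chemokine
CCL3,CCR1,chemokine
CCL3,CCR5,chemokine
CCL4,CCR5,chemokine
CCL5,CCR1,chemokine
CCL5,CCR5,chemokine
CCL19,CCR7,chemokine
CCL20,CCR6,chemokine
CCL21,CCR7,chemokine
CCL22,CCR4,chemokine
CX3CL1,CX3CR1,chemokine
LGALS9,HAVCR2,immune checkpoint
TNFRSF14,CD160,immune checkpoint
TNFRSF14,BTLA,immune checkpoint
CD274,PDCD1,immune checkpoint
PDCD1LG2,PDCD1,immune checkpoint
CD80,CTLA4,immune checkpoint
CD86,CTLA4,immune checkpoint
CD80,CD28,costimulation
CD86,CD28,costimulation
ICOSLG,ICOS,costimulation
CD40LG,CD40,costimulation
TNFSF9,TNFRSF9,costimulation
TNFSF4,TNFRSF4,costimulation
TNFSF13B,TNFRSF13B,B cell survival
TNFSF13,TNFRSF13B,B cell survival
TNF,TNFRSF1A,cytokine
TNF,TNFRSF1B,cytokine
IL1B,IL1R1,cytokine
IL1A,IL1R1,cytokine
IL6,IL6R,cytokine
IL10,IL10RA,cytokine
IL15,IL15RA,cytokine
IL18,IL18R1,cytokine
IFNG,IFNGR1,cytokine
TGFB1,TGFBR1,TGF-beta
TGFB1,TGFBR2,TGF-beta
TGFB2,TGFBR2,TGF-beta
TGFB3,TGFBR2,TGF-beta
BMP2,BMPR1A,TGF-beta
BMP4,BMPR1A,TGF-beta
GDF15,TGFBR2,TGF-beta
VEGFA,KDR,angiogenesis
VEGFA,FLT1,angiogenesis
VEGFB,FLT1,angiogenesis
VEGFC,FLT4,angiogenesis
PGF,FLT1,angiogenesis
ANGPT1,TEK,angiogenesis
ANGPT2,TEK,angiogenesis
DLL4,NOTCH1,Notch
DLL1,NOTCH1,Notch
JAG1,NOTCH1,Notch
JAG1,NOTCH2,Notch
JAG2,NOTCH1,Notch
EGF,EGFR,growth factor
TGFA,EGFR,growth factor
AREG,EGFR,growth factor
HBEGF,EGFR,growth factor
EREG,EGFR,growth factor
NRG1,ERBB3,growth factor
HGF,MET,growth factor
IGF1,IGF1R,growth factor
IGF2,IGF1R,growth factor
FGF2,FGFR1,growth factor
FGF7,FGFR2,growth factor
FGF10,FGFR2,growth factor
PDGFA,PDGFRA,growth factor
PDGFB,PDGFRB,growth factor
PDGFC,PDGFRA,growth factor
PDGFD,PDGFRB,growth factor
CSF1,CSF1R,myeloid growth
CSF2,CSF2RA,myeloid growth
CSF3,CSF3R,myeloid growth
FLT3LG,FLT3,dendritic cell growth
KITLG,KIT,stem cell factor
COL1A1,ITGA1,integrin-collagen
COL1A1,ITGA2,integrin-collagen
COL1A1,DDR1,collagen receptor
COL1A2,ITGA1,integrin-collagen
COL3A1,DDR1,collagen receptor
COL4A1,ITGA1,integrin-collagen
COL6A1,ITGA1,integrin-collagen
FN1,ITGA5,integrin-fibronectin
FN1,ITGAV,integrin-fibronectin
FN1,ITGB1,integrin-fibronectin
VTN,ITGAV,integrin-vitronectin
THBS1,CD47,thrombospondin
THBS1,CD36,thrombospondin
THBS2,CD36,thrombospondin
SPP1,CD44,osteopontin
SPP1,ITGAV,osteopontin
SPP1,ITGB3,osteopontin
LAMB1,ITGA6,integrin-laminin
LAMC1,ITGA6,integrin-laminin
TNC,ITGA9,integrin-tenascin
CTHRC1,FZD5,collagen triple helix
POSTN,ITGAV,periostin
POSTN,ITGB3,periostin
MDK,NCL,midkine
MDK,SDC1,midkine
PTN,SDC1,pleiotrophin
PTN,PTPRZ1,pleiotrophin
MIF,CD74,macrophage inhibition
APP,CD74,amyloid
GRN,SORT1,progranulin
ICAM1,ITGAL,adhesion
ICAM1,ITGAM,adhesion
VCAM1,ITGA4,adhesion
SELE,CD44,selectin
SELP,SELPLG,selectin
SELL,SELPLG,selectin
CDH1,ITGAE,adhesion
CD55,ADGRE5,adhesion
PECAM1,PECAM1,homotypic adhesion
ESAM,ESAM,homotypic adhesion
CDH5,CDH5,homotypic adhesion
EFNA1,EPHA2,ephrin
EFNB1,EPHB2,ephrin
EFNB2,EPHB4,ephrin
SEMA3A,NRP1,semaphorin
SEMA4D,PLXNB1,semaphorin
SLIT2,ROBO1,axon guidance
NTN1,DCC,axon guidance
GAS6,AXL,TAM receptor
PROS1,AXL,TAM receptor
GAS6,MERTK,TAM receptor
ADM,CALCRL,adrenomedullin
EDN1,EDNRA,endothelin
EDN1,EDNRB,endothelin
NPPB,NPR1,natriuretic
APLN,APLNR,apelin
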