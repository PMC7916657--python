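# FLT3-NPM1-DNMT3A AML module (synthetic reconstruction from canonical AML
# signaling biology: FLT3 -> STAT5 / PI3K-AKT / RAS-MAPK axes, NPM1 -> ARF-p53
# axis, DNMT3A -| HOXA9-MEIS1 axis). 21 protein nodes, 3 hallmark phenotypes.
FLT3	up-regulates	STAT5
FLT3	up-regulates	PI3K
FLT3	up-regulates	RAS
RAS	up-regulates	RAF
RAF	up-regulates	MEK
MEK	up-regulates	ERK
PI3K	up-regulates	AKT
AKT	up-regulates	MTOR
AKT	down-regulates	FOXO3
AKT	up-regulates	MDM2
ERK	up-regulates	MYC
ERK	down-regulates	CEBPA
STAT5	up-regulates	MYC
STAT5	up-regulates	BCL2
NPM1	up-regulates	CDKN2A
NPM1	up-regulates	TP53
CDKN2A	down-regulates	MDM2
MDM2	down-regulates	TP53
DNMT3A	down-regulates	HOXA9
HOXA9	up-regulates	MEIS1
CEBPA	up-regulates	SPI1
MYC	up-regulates	proliferation
MTOR	up-regulates	proliferation
STAT5	up-regulates	proliferation
MEIS1	up-regulates	proliferation
TP53	down-regulates	proliferation
CEBPA	up-regulates	differentiation
SPI1	up-regulates	differentiation
HOXA9	down-regulates	differentiation
TP53	up-regulates	apoptosis
FOXO3	up-regulates	apoptosis
BCL2	down-regulates	apoptosis
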