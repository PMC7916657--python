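disgenet_aml
BAALC
BCOR
CEBPA
DNMT3A
ERG
ETV6
EZH2
GATA2
IDH1
JAK2
MN1
NF1
NPM1
RUNX1
SMC1A
SMC3
SRSF2
TP53
U2AF1
WT1
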