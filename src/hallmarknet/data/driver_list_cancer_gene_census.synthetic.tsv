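cancer_gene_census
ASXL1
CBFB
CEBPA
DNMT3A
EZH2
FLT3
GATA2
KDM6A
KIT
KMT2C
KRAS
MPL
MYC
NF1
NOTCH1
NPM1
RAD21
RUNX1
SMC1A
TET2
U2AF1
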