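tcga_laml
BCOR
CBL
DNMT3A
FAM5C
FLT3
IDH1
IDH2
JAK2
MIR142
NRAS
PHF6
PTPN11
RUNX1
SF3B1
SMC3
SRSF2
STAG2
TP53
WT1
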