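papaemmanuil_nejm
ASXL1
CBL
CUX1
FLT3
GNB1
IDH2
KDM6A
KIT
KRAS
MPL
NPM1
NRAS
PHF6
PTPN11
RAD21
SF3B1
STAG2
TET2
TP53
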