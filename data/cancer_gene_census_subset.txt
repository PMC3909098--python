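# Synthetic subset of well-known cancer-gene census symbols (hand-curated
# stand-in for a user-supplied census download; one symbol per line).
ABL1
AKT1
ALK
APC
ATM
BRAF
BRCA1
BRCA2
CDH1
CDKN2A
CHCHD7
CTNNB1
EGFR
ERBB2
EZH2
FLT3
IDH1
IDH2
JAK2
KIT
KRAS
MET
MLH1
MYC
NF1
NOTCH1
NPM1
NRAS
PICALM
PTEN
RB1
RET
RUNX1
SF3B1
SMAD4
SRSF2
STK11
TET2
TP53
U2AF1
VHL
WT1
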