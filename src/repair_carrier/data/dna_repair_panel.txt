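# Default DNA-repair gene panel.
#
# The 17 genes in which qualifying variants were observed in the packaged
# case-variant table, extended with canonical DNA-repair and cancer-
# predisposition genes commonly included in germline panels. The full
# 175-gene panel used in the original screen is not published; supply your
# own panel file for faithful reuse.
#
# observed genes
ATM
BRCA1
CHEK2
ERCC3
FAN1
FANCM
HLTF
MRE11A
MUTYH
NEIL1
NTHL1
POLG
POLL
RAD18
RECQL
RECQL5
TP53
# canonical extension
BRCA2
PALB2
BRIP1
NBN
RAD50
RAD51
RAD51B
RAD51C
RAD51D
BARD1
BLM
WRN
ATR
CHEK1
MLH1
MSH2
MSH3
MSH6
PMS2
EXO1
FANCA
FANCC
FANCD2
ERCC2
ERCC4
ERCC5
XRCC2
XRCC3
GEN1
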