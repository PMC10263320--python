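# Default CYCLOPS seed genes: core clock genes plus canonical rhythmic
# output genes shared across peripheral tissues. One symbol per line.
ARNTL
ARNTL2
NPAS2
CLOCK
NR1D1
NR1D2
PER1
PER2
PER3
CRY1
CRY2
DBP
TEF
HLF
NFIL3
RORC
RORA
BHLHE40
BHLHE41
CIART
WEE1
NAMPT
USP2
TSC22D3
STK35
DTX4
HERPUD1
POR
LEO1
COQ10B
FMO2
ANGPTL2
SLC16A1
PDK4
LONRF3
GRAMD4
TP53INP2
CDKN1A
ETV6
KLF9
KLF13
NEDD9
ZBTB16
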