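DUSP6
RPS6KA1
PIM1
PIN1
MAPK1
APEX1
TP53
NBN
CHEK1
CHEK2
ATM
VDR
CYP1B1
TARDBP
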