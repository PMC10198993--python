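ATM
CHEK2
PCNA
TP53
CHEK1
TP53BP1
MCM6
CDT1
APEX1
NBN
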