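DUSP6	apoptotic process
RPS6KA1	apoptotic process
PIM1	apoptotic process
PIN1	apoptotic process
MAPK1	apoptotic process
APEX1	apoptotic process
TP53	apoptotic process
NBN	apoptotic process
CHEK1	apoptotic process
CHEK2	apoptotic process
ATM	apoptotic process
VDR	apoptotic process
CYP1B1	apoptotic process
TARDBP	apoptotic process
PCNA	DNA replication
MCM6	DNA replication
CDT1	DNA replication licensing
TP53BP1	DNA damage response
CYP1A1	xenobiotic metabolic process
CYP1A2	xenobiotic metabolic process
CYP2C19	xenobiotic metabolic process
CYP2D6	xenobiotic metabolic process
CYP3A4	xenobiotic metabolic process
POLH	translesion synthesis
GMNN	DNA replication licensing
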