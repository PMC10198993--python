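ABCG2	DUSP6	950
ADORA3	RPS6KA1	950
ALB	TDP1	450
ALDH1A1	DUSP6	950
APEX1	ATM	900
APEX1	CDT1	900
APEX1	CHEK1	900
APEX1	CHEK2	900
APEX1	MCM6	900
APEX1	NBN	900
APEX1	PCNA	900
APEX1	PIN1	800
APEX1	TP53	900
APEX1	TP53BP1	900
ATM	CDT1	900
ATM	CHEK1	900
ATM	CHEK2	900
ATM	CYP1A1	800
ATM	CYP1A2	800
ATM	CYP1B1	800
ATM	CYP2C19	800
ATM	CYP2D6	800
ATM	CYP3A4	800
ATM	MAPK1	800
ATM	MCM6	900
ATM	NBN	900
ATM	PCNA	900
ATM	PIM1	800
ATM	PIN1	800
ATM	TP53	900
ATM	TP53BP1	900
ATXN2	RPS6KA1	950
CBX1	GMNN	620
CBX1	KDM4E	580
CBX1	MEN1	580
CBX1	VDR	620
CDT1	CHEK1	900
CDT1	CHEK2	900
CDT1	MCM6	900
CDT1	NBN	900
CDT1	PCNA	900
CDT1	PIM1	800
CDT1	PIN1	800
CDT1	TP53	900
CDT1	TP53BP1	900
CHEK1	CHEK2	900
CHEK1	CYP2D6	800
CHEK1	CYP3A4	800
CHEK1	MAPK1	800
CHEK1	MCM6	900
CHEK1	NBN	900
CHEK1	PCNA	900
CHEK1	PIM1	800
CHEK1	PIN1	800
CHEK1	TP53	900
CHEK1	TP53BP1	900
CHEK2	CYP1A2	800
CHEK2	CYP1B1	800
CHEK2	CYP2C19	800
CHEK2	CYP2D6	800
CHEK2	CYP3A4	800
CHEK2	MAPK1	800
CHEK2	MCM6	900
CHEK2	NBN	900
CHEK2	PCNA	900
CHEK2	PIM1	800
CHEK2	PIN1	800
CHEK2	TP53	900
CHEK2	TP53BP1	900
CYP1B1	PCNA	800
CYP2C19	PCNA	800
CYP2C19	TP53	800
CYP2D6	PCNA	800
CYP2D6	TP53	800
CYP3A4	PCNA	800
CYP3A4	TP53	800
CYP3A4	TP53BP1	800
EGFR	RGS4	450
GAPDH	MEN1	450
GMNN	KDM4E	620
GMNN	NBN	850
INS	VDR	450
KDM4E	MEN1	620
MAPK1	MCM6	800
MAPK1	PCNA	800
MAPK1	TP53	800
MAPK1	TP53BP1	800
MCM6	NBN	900
MCM6	PCNA	900
MCM6	PIM1	800
MCM6	PIN1	800
MCM6	TP53	900
MCM6	TP53BP1	900
MEN1	POLH	620
MEN1	RGS4	580
MYC	POLH	450
NBN	PCNA	900
NBN	TP53	900
NBN	TP53BP1	900
PCNA	PIM1	800
PCNA	PIN1	800
PCNA	TP53	900
PCNA	TP53BP1	900
PIM1	TP53	800
PIM1	TP53BP1	800
PIN1	TP53	800
PIN1	TP53BP1	800
POLH	RGS4	620
POLH	TARDBP	580
RGS4	TARDBP	620
TARDBP	TAS2R31	620
TAS2R31	TDP1	620
TAS2R31	VDR	580
TDP1	VDR	620
TP53	TP53BP1	900
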