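gene	node	use_rna
EGF	EGF	1
HGF	HGF	1
FGF2	FGF	1
NRG1	NRG1	1
SOX10	SOX10	1
ATM	ATM	0
EGFR	EGFR	1
ERBB2	ERBB2	1
ERBB3	ERBB3	1
MET	MET	1
FGFR2	FGFR2	1
GRB2	GRB2	1
SOS1	SOS	1
GAB1	GAB1	1
SPRY2	SPRY	1
NRAS	RAS	1
KRAS	RAS	1
HRAS	RAS	1
BRAF	BRAF	0
RAF1	CRAF	1
MAP2K1	MEK	1
MAPK1	ERK	1
PIK3CA	PI3K	1
PTEN	PTEN	1
PDPK1	PDPK1	1
AKT1	AKT	1
MTOR	mTOR	1
RPS6KB1	p70	1
TP53	p53	0
CDKN1A	p21	1
FOXD3	FOXD3	1
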