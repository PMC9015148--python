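residue	chi1	chi2	chi3	chi4	prob
ALA					1.0000000000
ARG	-60.0	-60.0	180.0	180.0	0.1111111111
ARG	-60.0	60.0	180.0	180.0	0.1111111111
ARG	-60.0	180.0	180.0	180.0	0.1111111111
ARG	60.0	-60.0	180.0	180.0	0.1111111111
ARG	60.0	60.0	180.0	180.0	0.1111111111
ARG	60.0	180.0	180.0	180.0	0.1111111111
ARG	180.0	-60.0	180.0	180.0	0.1111111111
ARG	180.0	60.0	180.0	180.0	0.1111111111
ARG	180.0	180.0	180.0	180.0	0.1111111111
ASN	-60.0	-60.0			0.1111111111
ASN	-60.0	60.0			0.1111111111
ASN	-60.0	180.0			0.1111111111
ASN	60.0	-60.0			0.1111111111
ASN	60.0	60.0			0.1111111111
ASN	60.0	180.0			0.1111111111
ASN	180.0	-60.0			0.1111111111
ASN	180.0	60.0			0.1111111111
ASN	180.0	180.0			0.1111111111
ASP	-60.0	-60.0			0.1111111111
ASP	-60.0	60.0			0.1111111111
ASP	-60.0	180.0			0.1111111111
ASP	60.0	-60.0			0.1111111111
ASP	60.0	60.0			0.1111111111
ASP	60.0	180.0			0.1111111111
ASP	180.0	-60.0			0.1111111111
ASP	180.0	60.0			0.1111111111
ASP	180.0	180.0			0.1111111111
CYS	-60.0				0.3333333333
CYS	60.0				0.3333333333
CYS	180.0				0.3333333333
GLN	-60.0	-60.0	180.0		0.1111111111
GLN	-60.0	60.0	180.0		0.1111111111
GLN	-60.0	180.0	180.0		0.1111111111
GLN	60.0	-60.0	180.0		0.1111111111
GLN	60.0	60.0	180.0		0.1111111111
GLN	60.0	180.0	180.0		0.1111111111
GLN	180.0	-60.0	180.0		0.1111111111
GLN	180.0	60.0	180.0		0.1111111111
GLN	180.0	180.0	180.0		0.1111111111
GLU	-60.0	-60.0	180.0		0.1111111111
GLU	-60.0	60.0	180.0		0.1111111111
GLU	-60.0	180.0	180.0		0.1111111111
GLU	60.0	-60.0	180.0		0.1111111111
GLU	60.0	60.0	180.0		0.1111111111
GLU	60.0	180.0	180.0		0.1111111111
GLU	180.0	-60.0	180.0		0.1111111111
GLU	180.0	60.0	180.0		0.1111111111
GLU	180.0	180.0	180.0		0.1111111111
GLY					1.0000000000
HIS	-60.0	-60.0			0.1111111111
HIS	-60.0	60.0			0.1111111111
HIS	-60.0	180.0			0.1111111111
HIS	60.0	-60.0			0.1111111111
HIS	60.0	60.0			0.1111111111
HIS	60.0	180.0			0.1111111111
HIS	180.0	-60.0			0.1111111111
HIS	180.0	60.0			0.1111111111
HIS	180.0	180.0			0.1111111111
ILE	-60.0	-60.0			0.1111111111
ILE	-60.0	60.0			0.1111111111
ILE	-60.0	180.0			0.1111111111
ILE	60.0	-60.0			0.1111111111
ILE	60.0	60.0			0.1111111111
ILE	60.0	180.0			0.1111111111
ILE	180.0	-60.0			0.1111111111
ILE	180.0	60.0			0.1111111111
ILE	180.0	180.0			0.1111111111
LEU	-60.0	-60.0			0.1111111111
LEU	-60.0	60.0			0.1111111111
LEU	-60.0	180.0			0.1111111111
LEU	60.0	-60.0			0.1111111111
LEU	60.0	60.0			0.1111111111
LEU	60.0	180.0			0.1111111111
LEU	180.0	-60.0			0.1111111111
LEU	180.0	60.0			0.1111111111
LEU	180.0	180.0			0.1111111111
LYS	-60.0	-60.0	180.0	180.0	0.1111111111
LYS	-60.0	60.0	180.0	180.0	0.1111111111
LYS	-60.0	180.0	180.0	180.0	0.1111111111
LYS	60.0	-60.0	180.0	180.0	0.1111111111
LYS	60.0	60.0	180.0	180.0	0.1111111111
LYS	60.0	180.0	180.0	180.0	0.1111111111
LYS	180.0	-60.0	180.0	180.0	0.1111111111
LYS	180.0	60.0	180.0	180.0	0.1111111111
LYS	180.0	180.0	180.0	180.0	0.1111111111
MET	-60.0	-60.0	180.0		0.1111111111
MET	-60.0	60.0	180.0		0.1111111111
MET	-60.0	180.0	180.0		0.1111111111
MET	60.0	-60.0	180.0		0.1111111111
MET	60.0	60.0	180.0		0.1111111111
MET	60.0	180.0	180.0		0.1111111111
MET	180.0	-60.0	180.0		0.1111111111
MET	180.0	60.0	180.0		0.1111111111
MET	180.0	180.0	180.0		0.1111111111
PHE	-60.0	-60.0			0.1111111111
PHE	-60.0	60.0			0.1111111111
PHE	-60.0	180.0			0.1111111111
PHE	60.0	-60.0			0.1111111111
PHE	60.0	60.0			0.1111111111
PHE	60.0	180.0			0.1111111111
PHE	180.0	-60.0			0.1111111111
PHE	180.0	60.0			0.1111111111
PHE	180.0	180.0			0.1111111111
PRO					1.0000000000
SER	-60.0				0.3333333333
SER	60.0				0.3333333333
SER	180.0				0.3333333333
THR	-60.0				0.3333333333
THR	60.0				0.3333333333
THR	180.0				0.3333333333
TRP	-60.0	-60.0			0.1111111111
TRP	-60.0	60.0			0.1111111111
TRP	-60.0	180.0			0.1111111111
TRP	60.0	-60.0			0.1111111111
TRP	60.0	60.0			0.1111111111
TRP	60.0	180.0			0.1111111111
TRP	180.0	-60.0			0.1111111111
TRP	180.0	60.0			0.1111111111
TRP	180.0	180.0			0.1111111111
TYR	-60.0	-60.0			0.1111111111
TYR	-60.0	60.0			0.1111111111
TYR	-60.0	180.0			0.1111111111
TYR	60.0	-60.0			0.1111111111
TYR	60.0	60.0			0.1111111111
TYR	60.0	180.0			0.1111111111
TYR	180.0	-60.0			0.1111111111
TYR	180.0	60.0			0.1111111111
TYR	180.0	180.0			0.1111111111
VAL	-60.0				0.3333333333
VAL	60.0				0.3333333333
VAL	180.0				0.3333333333
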