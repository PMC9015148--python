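residue	atom	element	charge
ALA	N	N	-0.47
ALA	CA	C	0.47
ALA	C	C	0.51
ALA	O	O	-0.51
ALA	CB	C	0.00
ARG	N	N	-0.47
ARG	CA	C	0.47
ARG	C	C	0.51
ARG	O	O	-0.51
ARG	CB	C	0.00
ARG	CG	C	0.00
ARG	CD	C	0.20
ARG	NE	N	-0.40
ARG	CZ	C	0.60
ARG	NH1	N	0.30
ARG	NH2	N	0.30
ASN	N	N	-0.47
ASN	CA	C	0.47
ASN	C	C	0.51
ASN	O	O	-0.51
ASN	CB	C	0.00
ASN	CG	C	0.55
ASN	OD1	O	-0.55
ASN	ND2	N	0.00
ASP	N	N	-0.47
ASP	CA	C	0.47
ASP	C	C	0.51
ASP	O	O	-0.51
ASP	CB	C	0.00
ASP	CG	C	0.36
ASP	OD1	O	-0.68
ASP	OD2	O	-0.68
CYS	N	N	-0.47
CYS	CA	C	0.47
CYS	C	C	0.51
CYS	O	O	-0.51
CYS	CB	C	0.10
CYS	SG	S	-0.10
GLN	N	N	-0.47
GLN	CA	C	0.47
GLN	C	C	0.51
GLN	O	O	-0.51
GLN	CB	C	0.00
GLN	CG	C	0.00
GLN	CD	C	0.55
GLN	OE1	O	-0.55
GLN	NE2	N	0.00
GLU	N	N	-0.47
GLU	CA	C	0.47
GLU	C	C	0.51
GLU	O	O	-0.51
GLU	CB	C	0.00
GLU	CG	C	0.00
GLU	CD	C	0.36
GLU	OE1	O	-0.68
GLU	OE2	O	-0.68
GLY	N	N	-0.47
GLY	CA	C	0.47
GLY	C	C	0.51
GLY	O	O	-0.51
HIS	N	N	-0.47
HIS	CA	C	0.47
HIS	C	C	0.51
HIS	O	O	-0.51
HIS	CB	C	0.00
HIS	CG	C	0.10
HIS	ND1	N	-0.30
HIS	CD2	C	0.20
HIS	CE1	C	0.30
HIS	NE2	N	-0.30
ILE	N	N	-0.47
ILE	CA	C	0.47
ILE	C	C	0.51
ILE	O	O	-0.51
ILE	CB	C	0.00
ILE	CG1	C	0.00
ILE	CG2	C	0.00
ILE	CD1	C	0.00
LEU	N	N	-0.47
LEU	CA	C	0.47
LEU	C	C	0.51
LEU	O	O	-0.51
LEU	CB	C	0.00
LEU	CG	C	0.00
LEU	CD1	C	0.00
LEU	CD2	C	0.00
LYS	N	N	-0.47
LYS	CA	C	0.47
LYS	C	C	0.51
LYS	O	O	-0.51
LYS	CB	C	0.00
LYS	CG	C	0.00
LYS	CD	C	0.00
LYS	CE	C	0.25
LYS	NZ	N	0.75
MET	N	N	-0.47
MET	CA	C	0.47
MET	C	C	0.51
MET	O	O	-0.51
MET	CB	C	0.00
MET	CG	C	0.06
MET	SD	S	-0.12
MET	CE	C	0.06
PHE	N	N	-0.47
PHE	CA	C	0.47
PHE	C	C	0.51
PHE	O	O	-0.51
PHE	CB	C	0.00
PHE	CG	C	0.00
PHE	CD1	C	0.00
PHE	CD2	C	0.00
PHE	CE1	C	0.00
PHE	CE2	C	0.00
PHE	CZ	C	0.00
PRO	N	N	-0.47
PRO	CA	C	0.47
PRO	C	C	0.51
PRO	O	O	-0.51
PRO	CB	C	0.00
PRO	CG	C	0.00
PRO	CD	C	0.00
SER	N	N	-0.47
SER	CA	C	0.47
SER	C	C	0.51
SER	O	O	-0.51
SER	CB	C	0.25
SER	OG	O	-0.25
THR	N	N	-0.47
THR	CA	C	0.47
THR	C	C	0.51
THR	O	O	-0.51
THR	CB	C	0.25
THR	OG1	O	-0.25
THR	CG2	C	0.00
TRP	N	N	-0.47
TRP	CA	C	0.47
TRP	C	C	0.51
TRP	O	O	-0.51
TRP	CB	C	0.00
TRP	CG	C	0.00
TRP	CD1	C	0.15
TRP	CD2	C	0.00
TRP	NE1	N	-0.30
TRP	CE2	C	0.15
TRP	CE3	C	0.00
TRP	CZ2	C	0.00
TRP	CZ3	C	0.00
TRP	CH2	C	0.00
TYR	N	N	-0.47
TYR	CA	C	0.47
TYR	C	C	0.51
TYR	O	O	-0.51
TYR	CB	C	0.00
TYR	CG	C	0.00
TYR	CD1	C	0.00
TYR	CD2	C	0.00
TYR	CE1	C	0.00
TYR	CE2	C	0.00
TYR	CZ	C	0.25
TYR	OH	O	-0.25
VAL	N	N	-0.47
VAL	CA	C	0.47
VAL	C	C	0.51
VAL	O	O	-0.51
VAL	CB	C	0.00
VAL	CG1	C	0.00
VAL	CG2	C	0.00
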