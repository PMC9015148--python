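residue	atom	element	parent	angle_ref	dihedral_ref	bond	angle	dihedral
ALA	CB	C	CA	N	C	1.521	110.5	-122.6
ARG	CB	C	CA	N	C	1.521	110.5	-122.6
ARG	CG	C	CB	CA	N	1.52	114.1	chi1
ARG	CD	C	CG	CB	CA	1.52	111.3	chi2
ARG	NE	N	CD	CG	CB	1.461	112.0	chi3
ARG	CZ	C	NE	CD	CG	1.329	124.2	chi4
ARG	NH1	N	CZ	NE	CD	1.326	120.0	0
ARG	NH2	N	CZ	NE	CD	1.326	120.0	180
ASN	CB	C	CA	N	C	1.521	110.5	-122.6
ASN	CG	C	CB	CA	N	1.516	112.6	chi1
ASN	OD1	O	CG	CB	CA	1.231	120.8	chi2
ASN	ND2	N	CG	CB	CA	1.328	116.4	chi2+180
ASP	CB	C	CA	N	C	1.521	110.5	-122.6
ASP	CG	C	CB	CA	N	1.516	112.6	chi1
ASP	OD1	O	CG	CB	CA	1.249	118.4	chi2
ASP	OD2	O	CG	CB	CA	1.249	118.4	chi2+180
CYS	CB	C	CA	N	C	1.521	110.5	-122.6
CYS	SG	S	CB	CA	N	1.808	113.8	chi1
GLN	CB	C	CA	N	C	1.521	110.5	-122.6
GLN	CG	C	CB	CA	N	1.52	114.1	chi1
GLN	CD	C	CG	CB	CA	1.516	112.6	chi2
GLN	OE1	O	CD	CG	CB	1.231	120.8	chi3
GLN	NE2	N	CD	CG	CB	1.328	116.4	chi3+180
GLU	CB	C	CA	N	C	1.521	110.5	-122.6
GLU	CG	C	CB	CA	N	1.52	114.1	chi1
GLU	CD	C	CG	CB	CA	1.516	112.6	chi2
GLU	OE1	O	CD	CG	CB	1.249	118.4	chi3
GLU	OE2	O	CD	CG	CB	1.249	118.4	chi3+180
HIS	CB	C	CA	N	C	1.521	110.5	-122.6
HIS	CG	C	CB	CA	N	1.504	113.8	chi1
HIS	ND1	N	CG	CB	CA	1.378	122.7	chi2
HIS	CD2	C	CG	CB	CA	1.354	131.0	chi2+180
HIS	CE1	C	ND1	CG	CB	1.321	109.0	180
HIS	NE2	N	CD2	CG	CB	1.374	107.2	180
ILE	CB	C	CA	N	C	1.521	110.5	-122.6
ILE	CG1	C	CB	CA	N	1.53	110.4	chi1
ILE	CG2	C	CB	CA	N	1.521	110.5	chi1-120
ILE	CD1	C	CG1	CB	CA	1.513	113.8	chi2
LEU	CB	C	CA	N	C	1.521	110.5	-122.6
LEU	CG	C	CB	CA	N	1.53	116.3	chi1
LEU	CD1	C	CG	CB	CA	1.521	110.7	chi2
LEU	CD2	C	CG	CB	CA	1.521	110.7	chi2+120
LYS	CB	C	CA	N	C	1.521	110.5	-122.6
LYS	CG	C	CB	CA	N	1.52	114.1	chi1
LYS	CD	C	CG	CB	CA	1.52	111.3	chi2
LYS	CE	C	CD	CG	CB	1.52	111.3	chi3
LYS	NZ	N	CE	CD	CG	1.489	111.9	chi4
MET	CB	C	CA	N	C	1.521	110.5	-122.6
MET	CG	C	CB	CA	N	1.52	114.1	chi1
MET	SD	S	CG	CB	CA	1.803	112.7	chi2
MET	CE	C	SD	CG	CB	1.791	100.9	chi3
PHE	CB	C	CA	N	C	1.521	110.5	-122.6
PHE	CG	C	CB	CA	N	1.502	113.8	chi1
PHE	CD1	C	CG	CB	CA	1.384	120.8	chi2
PHE	CD2	C	CG	CB	CA	1.384	120.8	chi2+180
PHE	CE1	C	CD1	CG	CB	1.382	120.8	180
PHE	CE2	C	CD2	CG	CB	1.382	120.8	180
PHE	CZ	C	CE1	CD1	CG	1.372	120.1	0
PRO	CB	C	CA	N	C	1.521	110.5	-122.6
PRO	CG	C	CB	CA	N	1.492	104.5	30
PRO	CD	C	CG	CB	CA	1.503	106.1	-35
SER	CB	C	CA	N	C	1.521	110.5	-122.6
SER	OG	O	CB	CA	N	1.417	110.8	chi1
THR	CB	C	CA	N	C	1.521	110.5	-122.6
THR	OG1	O	CB	CA	N	1.433	109.6	chi1
THR	CG2	C	CB	CA	N	1.521	110.5	chi1-120
TRP	CB	C	CA	N	C	1.521	110.5	-122.6
TRP	CG	C	CB	CA	N	1.498	113.6	chi1
TRP	CD1	C	CG	CB	CA	1.365	126.9	chi2
TRP	CD2	C	CG	CB	CA	1.433	126.6	chi2+180
TRP	NE1	N	CD1	CG	CB	1.374	110.2	180
TRP	CE2	C	CD2	CG	CB	1.409	107.2	180
TRP	CE3	C	CD2	CG	CB	1.398	133.9	0
TRP	CZ2	C	CE2	CD2	CG	1.394	122.4	180
TRP	CZ3	C	CE3	CD2	CG	1.382	118.6	180
TRP	CH2	C	CZ2	CE2	CD2	1.368	117.5	180
TYR	CB	C	CA	N	C	1.521	110.5	-122.6
TYR	CG	C	CB	CA	N	1.502	113.8	chi1
TYR	CD1	C	CG	CB	CA	1.384	120.8	chi2
TYR	CD2	C	CG	CB	CA	1.384	120.8	chi2+180
TYR	CE1	C	CD1	CG	CB	1.382	120.8	180
TYR	CE2	C	CD2	CG	CB	1.382	120.8	180
TYR	CZ	C	CE1	CD1	CG	1.372	120.1	0
TYR	OH	O	CZ	CE1	CD1	1.376	119.9	180
VAL	CB	C	CA	N	C	1.521	110.5	-122.6
VAL	CG1	C	CB	CA	N	1.527	110.5	chi1
VAL	CG2	C	CB	CA	N	1.527	110.5	chi1+120
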