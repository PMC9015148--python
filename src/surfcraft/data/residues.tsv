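residue	one_letter	formal_charge	n_chi
ALA	A	0	0
ARG	R	1	4
ASN	N	0	2
ASP	D	-1	2
CYS	C	0	1
GLN	Q	0	3
GLU	E	-1	3
GLY	G	0	0
HIS	H	0	2
ILE	I	0	2
LEU	L	0	2
LYS	K	1	4
MET	M	0	3
PHE	F	0	2
PRO	P	0	0
SER	S	0	1
THR	T	0	1
TRP	W	0	2
TYR	Y	0	2
VAL	V	0	1
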