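# Residue/atom -> atomic-group assignment for standard amino acids.
# residue	atom	group
# Backbone: N->NH (PRO: N), CA->CH (GLY: CH2), C->C, O->O, OXT->O.
ALA	N	NH
ALA	CA	CH
ALA	C	C
ALA	O	O
ALA	OXT	O
ALA	CB	CH3
ARG	N	NH
ARG	CA	CH
ARG	C	C
ARG	O	O
ARG	OXT	O
ARG	CB	CH2
ARG	CG	CH2
ARG	CD	CH2
ARG	NE	NH
ARG	CZ	C
ARG	NH1	NH2
ARG	NH2	NH2
ASN	N	NH
ASN	CA	CH
ASN	C	C
ASN	O	O
ASN	OXT	O
ASN	CB	CH2
ASN	CG	C
ASN	OD1	O
ASN	ND2	NH2
ASP	N	NH
ASP	CA	CH
ASP	C	C
ASP	O	O
ASP	OXT	O
ASP	CB	CH2
ASP	CG	C
ASP	OD1	O
ASP	OD2	O
CYS	N	NH
CYS	CA	CH
CYS	C	C
CYS	O	O
CYS	OXT	O
CYS	CB	CH2
CYS	SG	SH
GLN	N	NH
GLN	CA	CH
GLN	C	C
GLN	O	O
GLN	OXT	O
GLN	CB	CH2
GLN	CG	CH2
GLN	CD	C
GLN	OE1	O
GLN	NE2	NH2
GLU	N	NH
GLU	CA	CH
GLU	C	C
GLU	O	O
GLU	OXT	O
GLU	CB	CH2
GLU	CG	CH2
GLU	CD	C
GLU	OE1	O
GLU	OE2	O
GLY	N	NH
GLY	CA	CH2
GLY	C	C
GLY	O	O
GLY	OXT	O
HIS	N	NH
HIS	CA	CH
HIS	C	C
HIS	O	O
HIS	OXT	O
HIS	CB	CH2
HIS	CG	C
HIS	ND1	NH
HIS	CD2	CH
HIS	CE1	CH
HIS	NE2	N
ILE	N	NH
ILE	CA	CH
ILE	C	C
ILE	O	O
ILE	OXT	O
ILE	CB	CH
ILE	CG1	CH2
ILE	CG2	CH3
ILE	CD1	CH3
LEU	N	NH
LEU	CA	CH
LEU	C	C
LEU	O	O
LEU	OXT	O
LEU	CB	CH2
LEU	CG	CH
LEU	CD1	CH3
LEU	CD2	CH3
LYS	N	NH
LYS	CA	CH
LYS	C	C
LYS	O	O
LYS	OXT	O
LYS	CB	CH2
LYS	CG	CH2
LYS	CD	CH2
LYS	CE	CH2
LYS	NZ	NH3
MET	N	NH
MET	CA	CH
MET	C	C
MET	O	O
MET	OXT	O
MET	CB	CH2
MET	CG	CH2
MET	SD	S
MET	CE	CH3
PHE	N	NH
PHE	CA	CH
PHE	C	C
PHE	O	O
PHE	OXT	O
PHE	CB	CH2
PHE	CG	C
PHE	CD1	CH
PHE	CD2	CH
PHE	CE1	CH
PHE	CE2	CH
PHE	CZ	CH
PRO	N	N
PRO	CA	CH
PRO	C	C
PRO	O	O
PRO	OXT	O
PRO	CB	CH2
PRO	CG	CH2
PRO	CD	CH2
SER	N	NH
SER	CA	CH
SER	C	C
SER	O	O
SER	OXT	O
SER	CB	CH2
SER	OG	OH
THR	N	NH
THR	CA	CH
THR	C	C
THR	O	O
THR	OXT	O
THR	CB	CH
THR	OG1	OH
THR	CG2	CH3
TRP	N	NH
TRP	CA	CH
TRP	C	C
TRP	O	O
TRP	OXT	O
TRP	CB	CH2
TRP	CG	C
TRP	CD1	CH
TRP	CD2	C
TRP	NE1	NH
TRP	CE2	C
TRP	CE3	CH
TRP	CZ2	CH
TRP	CZ3	CH
TRP	CH2	CH
TYR	N	NH
TYR	CA	CH
TYR	C	C
TYR	O	O
TYR	OXT	O
TYR	CB	CH2
TYR	CG	C
TYR	CD1	CH
TYR	CD2	CH
TYR	CE1	CH
TYR	CE2	CH
TYR	CZ	C
TYR	OH	OH
VAL	N	NH
VAL	CA	CH
VAL	C	C
VAL	O	O
VAL	OXT	O
VAL	CB	CH
VAL	CG1	CH3
VAL	CG2	CH3
TOY	BD	TOY
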