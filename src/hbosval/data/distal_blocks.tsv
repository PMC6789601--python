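# Distal-block table: residue type, chi1 gamma atom, distal-block atom names.
# The distal block is the terminal rigid chemical group of the side chain;
# its mass centroid defines the block-length feature. Edit and pass via
# --blocks to override.
ARG	CG	NE,CZ,NH1,NH2
ASN	CG	CG,OD1,ND2
ASP	CG	CG,OD1,OD2
CYS	SG	CB,SG
GLN	CG	CD,OE1,NE2
GLU	CG	CD,OE1,OE2
HIS	CG	CG,ND1,CD2,CE1,NE2
ILE	CG1	CG1,CD1
LEU	CG	CG,CD1,CD2
LYS	CG	CE,NZ
MET	CG	SD,CE
PHE	CG	CG,CD1,CD2,CE1,CE2,CZ
PRO	CG	CG,CD
SER	OG	CB,OG
THR	OG1	CB,OG1,CG2
TRP	CG	CG,CD1,CD2,NE1,CE2,CE3,CZ2,CZ3,CH2
TYR	CG	CG,CD1,CD2,CE1,CE2,CZ,OH
VAL	CG1	CB,CG1,CG2
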