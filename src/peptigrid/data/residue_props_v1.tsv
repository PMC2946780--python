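# peptigrid per-residue properties, version 1
# entropy_max: maximal configurational side-chain entropy penalty, kcal/mol,
#              paid in proportion to the buried fraction of the side chain
residue	letter	entropy_max
GLY	G	0.0
ALA	A	0.0
SER	S	0.9
CYS	C	0.6
THR	T	0.9
VAL	V	0.5
LEU	L	0.7
ILE	I	0.7
MET	M	1.6
PRO	P	0.0
PHE	F	0.9
TYR	Y	1.1
TRP	W	1.1
ASP	D	1.0
GLU	E	1.4
ASN	N	1.1
GLN	Q	1.5
LYS	K	1.9
ARG	R	2.1
HIS	H	0.9
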