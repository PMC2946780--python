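# peptigrid united-residue side-chain topology, version 1
# One row per side-chain pseudo-atom. Branched terminal groups are collapsed into
# single united atoms (e.g. LEU CD1/CD2 -> CD, PHE ring -> RC ring centroid).
# parent: atom this one is bonded to; blen/bang: bond length (A) and angle (deg)
# tors: which torsion drives the dihedral ("cb" = fixed improper off the backbone,
#       "chiN" = side-chain torsion N, "fix" = rigid offset from the parent frame)
# offset: degrees added to the driving torsion (branch atoms share a chi with an offset)
# donor/acceptor: hydrogen-bond roles (united-atom heavy-atom convention)
residue	atom	class	charge	parent	blen	bang	tors	offset	donor	acceptor
ALA	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
SER	CB	C_ALI	0.30	CA	1.53	110.5	cb	0	0	0
SER	OG	O_HYD	-0.30	CB	1.42	110.5	chi1	0	1	1
CYS	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
CYS	SG	S_THL	0.00	CB	1.81	112.0	chi1	0	0	0
THR	CB	C_ALI	0.30	CA	1.53	110.5	cb	0	0	0
THR	OG1	O_HYD	-0.30	CB	1.42	110.5	chi1	0	1	1
VAL	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
VAL	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
LEU	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
LEU	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
LEU	CD	C_ALI	0.00	CG	1.53	111.0	chi2	0	0	0
ILE	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
ILE	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
ILE	CD	C_ALI	0.00	CG	1.53	111.0	chi2	0	0	0
MET	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
MET	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
MET	SD	S_THL	0.00	CG	1.81	112.0	chi2	0	0	0
MET	CE	C_ALI	0.00	SD	1.79	100.0	chi3	0	0	0
PRO	CB	C_ALI	0.00	CA	1.53	103.0	cb	0	0	0
PRO	CG	C_ALI	0.00	CB	1.51	104.0	fix	30	0	0
PRO	CD	C_ALI	0.00	CG	1.51	106.0	fix	-35	0	0
PHE	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
PHE	RC	C_RNG	0.00	CB	2.92	114.0	chi1	0	0	0
TYR	CB	C_ALI	0.30	CA	1.53	110.5	cb	0	0	0
TYR	RC	C_RNG	0.00	CB	2.92	114.0	chi1	0	0	0
TYR	OH	O_HYD	-0.30	RC	2.75	170.0	fix	0	1	1
TRP	CB	C_ALI	0.10	CA	1.53	110.5	cb	0	0	0
TRP	RC	C_RNG	0.00	CB	3.20	114.0	chi1	0	0	0
TRP	NE1	N_AMD	-0.10	RC	2.10	150.0	fix	0	1	0
ASP	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
ASP	CG	C_CRB	0.30	CB	1.52	112.0	chi1	0	0	0
ASP	OD	O_NEG	-1.30	CG	1.25	120.0	chi2	0	0	1
GLU	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
GLU	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
GLU	CD	C_CRB	0.30	CG	1.52	112.0	chi2	0	0	0
GLU	OE	O_NEG	-1.30	CD	1.25	120.0	chi3	0	0	1
ASN	CB	C_ALI	0.30	CA	1.53	110.5	cb	0	0	0
ASN	CG	C_CRB	0.45	CB	1.52	112.0	chi1	0	0	0
ASN	OD1	O_CRB	-0.45	CG	1.23	120.0	chi2	0	0	1
ASN	ND2	N_AMD	-0.30	CG	1.33	116.0	chi2	180	1	0
GLN	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
GLN	CG	C_ALI	0.30	CB	1.53	111.0	chi1	0	0	0
GLN	CD	C_CRB	0.45	CG	1.52	112.0	chi2	0	0	0
GLN	OE1	O_CRB	-0.45	CD	1.23	120.0	chi3	0	0	1
GLN	NE2	N_AMD	-0.30	CD	1.33	116.0	chi3	180	1	0
LYS	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
LYS	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
LYS	CD	C_ALI	0.00	CG	1.53	111.0	chi2	0	0	0
LYS	CE	C_ALI	0.00	CD	1.53	111.0	chi3	0	0	0
LYS	NZ	N_POS	1.00	CE	1.49	111.0	chi4	0	1	0
ARG	CB	C_ALI	0.00	CA	1.53	110.5	cb	0	0	0
ARG	CG	C_ALI	0.00	CB	1.53	111.0	chi1	0	0	0
ARG	CD	C_ALI	0.00	CG	1.53	111.0	chi2	0	0	0
ARG	NE	N_AMD	-0.20	CD	1.46	111.0	chi3	0	1	0
ARG	CZ	C_CRB	0.40	NE	1.33	120.0	chi4	0	0	0
ARG	NH	N_POS	0.80	CZ	1.33	120.0	fix	0	1	0
HIS	CB	C_ALI	0.10	CA	1.53	110.5	cb	0	0	0
HIS	RC	C_RNG	0.00	CB	2.60	114.0	chi1	0	0	0
HIS	RN	N_AMD	-0.10	RC	1.70	150.0	fix	0	1	1
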