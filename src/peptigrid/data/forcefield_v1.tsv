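# peptigrid united-atom parameter table, version 1
# class: atom class label
# rmin_half: half of the Lennard-Jones minimum-energy pair distance for a homo pair, Angstrom
# eps: Lennard-Jones well depth, kcal/mol
# solv: atomic solvation parameter, kcal/(mol*A^2) (applied to solvent-accessible area)
# hydrophobic: hydrophobic-contact strength factor (0 = polar, pair strength is the product)
class	rmin_half	eps	solv	hydrophobic
C_ALI	2.00	0.15	0.025	1.0
C_ARO	1.95	0.15	0.025	1.0
C_RNG	2.40	0.18	0.025	1.0
C_CRB	1.90	0.10	0.000	0.0
N_AMD	1.75	0.16	-0.030	0.0
N_POS	1.75	0.16	-0.060	0.0
O_CRB	1.60	0.20	-0.030	0.0
O_HYD	1.65	0.20	-0.030	0.0
O_NEG	1.60	0.20	-0.060	0.0
S_THL	1.95	0.25	0.025	0.5
P_PRB	1.70	0.20	0.000	0.0
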