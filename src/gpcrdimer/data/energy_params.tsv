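# Generic pairwise-energy parameter table for the simplified interface model.
# Section LJ: per-element Lennard-Jones sigma (Angstrom) and epsilon
# (kcal/mol), combined with Lorentz-Berthelot rules. Section CHARGE: formal
# charges (e) placed on terminal sidechain atoms of ionizable residues;
# every unlisted atom is neutral. HIP denotes protonated histidine.
LJ	H	2.00	0.016
LJ	C	3.40	0.086
LJ	N	3.25	0.170
LJ	O	2.96	0.210
LJ	S	3.56	0.250
LJ	P	3.74	0.200
CHARGE	ASP	OD1	-0.5
CHARGE	ASP	OD2	-0.5
CHARGE	GLU	OE1	-0.5
CHARGE	GLU	OE2	-0.5
CHARGE	LYS	NZ	1.0
CHARGE	ARG	NH1	0.5
CHARGE	ARG	NH2	0.5
CHARGE	HIP	ND1	0.5
CHARGE	HIP	NE2	0.5
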