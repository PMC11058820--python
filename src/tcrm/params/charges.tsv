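# tcrm parameter set v1 -- reduced partial-charge set (heavy atoms, no hydrogens)
# backbone dipole on every residue; formal charges on Lys/Arg/Asp/Glu side chains
# (His neutral); terminal charges only when OXT is present (C-terminus).
# residue	atom	charge
*	N	-0.30
*	CA	0.30
*	C	0.45
*	O	-0.45
*	OXT	-0.50
LYS	NZ	1.00
ARG	NH1	0.50
ARG	NH2	0.50
ASP	OD1	-0.50
ASP	OD2	-0.50
GLU	OE1	-0.50
GLU	OE2	-0.50
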