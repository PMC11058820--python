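# tcrm parameter set v1 -- Lennard-Jones atom classes
# combination rules: rmin_ij = rmin_half_i + rmin_half_j; eps_ij = sqrt(eps_i*eps_j)
# class	rmin_half	epsilon
C	1.95	0.12
N	1.80	0.17
O	1.70	0.16
S	2.00	0.20
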