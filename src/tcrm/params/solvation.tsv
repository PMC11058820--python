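# tcrm parameter set v1 -- Gaussian-exclusion (Lazaridis-Karplus style) solvation
# class	dg_free	lambda	volume
C	0.60	3.5	23.7
N	-6.00	3.5	11.2
O	-6.00	3.5	10.8
S	-2.00	3.5	14.7
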