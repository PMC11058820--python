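# tcrm parameter set v1 -- solvent-accessibility radii (Chothia-style), Angstrom
# key	radius
name:C	1.76
element:C	1.87
element:N	1.65
element:O	1.40
element:S	1.85
element:P	1.90
element:H	1.00
default	1.80
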