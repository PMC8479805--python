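# Generic per-element Lennard-Jones parameters (GAFF-like) for the simplified
# molecular-mechanics interaction term. epsilon in kcal/mol, sigma in Angstrom.
# Combined with Lorentz-Berthelot rules.
# element	epsilon	sigma
H	0.0157	2.65
C	0.0860	3.40
N	0.1700	3.25
O	0.2100	2.96
S	0.2500	3.56
P	0.2000	3.74
F	0.0610	3.12
Cl	0.2650	3.47
Br	0.3200	3.60
I	0.4000	3.80
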