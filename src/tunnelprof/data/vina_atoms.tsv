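# Scoring-class van der Waals radii (Angstrom) per element, matching the
# published empirical docking score parameterization.
# element	radius
C	1.9
N	1.8
O	1.7
S	2.0
P	2.1
F	1.5
Cl	1.8
Br	2.0
I	2.2
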