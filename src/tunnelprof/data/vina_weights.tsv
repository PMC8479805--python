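# Term weights of the empirical pairwise scoring function.
# term	weight
gauss1	-0.035579
gauss2	-0.005156
repulsion	0.840245
hydrophobic	-0.035069
hbond	-0.587439
rotor	0.05846
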