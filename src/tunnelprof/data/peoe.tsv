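# PEOE (partial equalization of orbital electronegativities) parameters.
# chi(q) = a + b*q + c*q^2 per SYBYL atom type; values from the published
# Gasteiger-Marsili parameterization. P.3 is a later-literature extension
# (the original set had no phosphorus). Units: eV-like electronegativity scale.
# type	a	b	c
H	7.17	6.24	-0.56
C.3	7.98	9.18	1.88
C.2	8.79	9.32	1.51
C.ar	8.79	9.32	1.51
C.cat	8.79	9.32	1.51
C.1	10.39	9.45	0.73
N.3	11.54	10.82	1.36
N.4	11.54	10.82	1.36
N.am	12.87	11.15	0.85
N.pl3	12.87	11.15	0.85
N.2	12.87	11.15	0.85
N.ar	12.87	11.15	0.85
N.1	15.68	11.70	-0.27
O.3	14.18	12.92	1.39
O.2	17.07	13.79	0.47
O.co2	15.62	13.36	0.93
S.3	10.14	9.13	1.38
S.2	10.14	9.13	1.38
S.o	10.14	9.13	1.38
S.o2	10.14	9.13	1.38
P.3	8.90	8.24	0.96
F	14.66	13.85	2.31
Cl	11.00	9.69	1.35
Br	10.08	8.47	1.16
I	9.90	7.96	0.96
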