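# Bondi (1964) van der Waals radii, Angstrom
# element	radius
H	1.20
He	1.40
Li	1.82
C	1.70
N	1.55
O	1.52
F	1.47
Ne	1.54
Na	2.27
Mg	1.73
Si	2.10
P	1.80
S	1.80
Cl	1.75
Ar	1.88
K	2.75
Ni	1.63
Cu	1.40
Zn	1.39
Ga	1.87
As	1.85
Se	1.90
Br	1.85
Kr	2.02
Pd	1.63
Ag	1.72
Cd	1.58
In	1.93
Sn	2.17
Te	2.06
I	1.98
Xe	2.16
Pt	1.75
Au	1.66
Hg	1.55
Tl	1.96
Pb	2.02
U	1.86
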