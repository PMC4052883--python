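#amino_acid	dG_kcal_mol
A	1.94
C	-1.24
D	-10.95
E	-10.20
F	-0.76
G	2.39
H	-10.27
I	2.15
K	-9.52
L	2.28
M	-1.48
N	-9.68
Q	-9.38
R	-19.92
S	-5.06
T	-4.88
V	1.99
W	-5.88
Y	-6.11
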