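# source: Levitt M (1978) Biochemistry 17:4277-4285. Reverse-turn conformational preferences.
residue	value
A	0.77
C	0.81
D	1.41
E	0.99
F	0.59
G	1.64
H	0.68
I	0.51
K	0.96
L	0.58
M	0.41
N	1.28
P	1.91
Q	0.98
R	0.88
S	1.32
T	1.04
V	0.47
W	0.76
Y	1.05
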