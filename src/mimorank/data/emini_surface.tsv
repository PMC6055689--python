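# source: Emini EA, Hughes JV, Perlow DS, Boger J (1985) J Virol 55:836-839. Fractional surface probabilities.
residue	value
A	0.49
C	0.26
D	0.81
E	0.84
F	0.42
G	0.48
H	0.66
I	0.34
K	0.97
L	0.40
M	0.48
N	0.78
P	0.75
Q	0.84
R	0.95
S	0.65
T	0.70
V	0.36
W	0.51
Y	0.76
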