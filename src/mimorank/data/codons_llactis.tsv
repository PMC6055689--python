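# source: most frequent codon per amino acid, Lactococcus lactis subsp. lactis IL1403 codon usage (Kazusa CUTG); AT-rich firmicute preferences.
aa	codon
A	GCA
C	UGU
D	GAU
E	GAA
F	UUU
G	GGA
H	CAU
I	AUU
K	AAA
L	UUA
M	AUG
N	AAU
P	CCA
Q	CAA
R	CGU
S	UCA
T	ACA
V	GUU
W	UGG
Y	UAU
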