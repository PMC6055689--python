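# source: most frequent codon per amino acid, Homo sapiens codon usage (Kazusa CUTG).
aa	codon
A	GCC
C	UGC
D	GAC
E	GAG
F	UUC
G	GGC
H	CAC
I	AUC
K	AAG
L	CUG
M	AUG
N	AAC
P	CCC
Q	CAG
R	AGA
S	AGC
T	ACC
V	GUG
W	UGG
Y	UAC
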