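#codon	tai
AAA	0.0625
AAC	0.0625
AAG	0.0625
AAT	0.05
ACA	0.0625
ACC	0.1875
ACG	0.0625
ACT	0.1875
AGA	0.1875
AGC	0.125
AGG	0.125
AGT	0.275
ATA	0.0625
ATC	0.1875
ATG	0.0625
ATT	0.25
CAA	0.6875
CAC	0.075
CAG	0.125
CAT	0.1875
CCA	0.25
CCC	0.1
CCG	0.1875
CCT	0.1
CGA	0.25
CGC	0.25
CGG	0.0625
CGT	0.375
CTA	0.0625
CTC	0.075
CTG	0.0625
CTT	0.0625
GAA	0.3125
GAC	0.1875
GAG	0.125
GAT	0.6875
GCA	1.0
GCC	0.125
GCG	0.25
GCT	0.0625
GGA	0.0625
GGC	0.0625
GGG	0.625
GGT	0.25
GTA	0.125
GTC	0.125
GTG	0.05
GTT	0.0625
TAC	0.1875
TAT	0.125
TCA	0.6875
TCC	0.0625
TCG	0.275
TCT	0.125
TGC	0.25
TGG	0.1875
TGT	0.1
TTA	0.0625
TTC	0.125
TTG	0.1875
TTT	0.1875
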