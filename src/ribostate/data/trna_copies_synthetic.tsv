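#codon	copies
AAA	1
AAC	1
AAG	1
AAT	0
ACA	1
ACC	3
ACG	1
ACT	3
AGA	3
AGC	2
AGG	2
AGT	0
ATA	1
ATC	3
ATG	1
ATT	4
CAA	11
CAC	0
CAG	2
CAT	3
CCA	4
CCC	0
CCG	3
CCT	0
CGA	4
CGC	4
CGG	1
CGT	6
CTA	1
CTC	0
CTG	1
CTT	1
GAA	5
GAC	3
GAG	2
GAT	11
GCA	16
GCC	2
GCG	4
GCT	1
GGA	1
GGC	1
GGG	10
GGT	4
GTA	2
GTC	2
GTG	0
GTT	1
TAC	3
TAT	2
TCA	11
TCC	1
TCG	0
TCT	2
TGC	4
TGG	3
TGT	0
TTA	1
TTC	2
TTG	3
TTT	3
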