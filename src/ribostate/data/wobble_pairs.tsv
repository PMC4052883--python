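#wc_codon	wobble_codon	pairing
TTC	TTT	U-G
GAC	GAT	U-G
AAC	AAT	U-G
CAC	CAT	U-G
TAC	TAT	U-G
TGC	TGT	U-G
AGC	AGT	U-G
GGC	GGT	U-G
CCA	CCG	G-U
CTA	CTG	G-U
GCA	GCG	G-U
CGC	CGA	A-I
GCC	GCA	A-I
CCC	CCA	A-I
ACC	ACA	A-I
GTC	GTA	A-I
TCC	TCA	A-I
CGC	CGT	U-I
GCC	GCT	U-I
CCC	CCT	U-I
ACC	ACT	U-I
GTC	GTT	U-I
TCC	TCT	U-I
ATC	ATT	U-I
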