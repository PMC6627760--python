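# RNA-binding-protein sequence motifs scanned in pre-miRNA sequences.
# loop_restricted = 1: the protein binds the apical loop, so matches are
# searched in the loop subregion only; 0: whole precursor.
protein	pattern	loop_restricted
hnRNPA1	UAGGGAW	1
HuR	AUUUUUAUUUU	1
KSRP	GGGU	1
Lin28	GGAG	1
MBNL1	YGCY	1
MCPIP1	UGC	1
DGCR8	UGU	1
MATR3	AUCUU	1
ZC3H7	SMUANY	1
YBX1	CAUC	1
TRIM71	UAUAA	1
PTBP1/3	UUUUUCCNUCUUU	1
DDX17	VCAUCH	0
RBFOX	GCAUG	0
SMAD	CAGAC	0
CELF1/2	UGUNNNNNNNUGU	0
ZC3H10	GCAGCGC	0
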