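# Retinal-dystrophy gene panel entries for the genes carrying cohort findings.
# association: established_IRD | established_syndromic | candidate_gene
symbol	association	modes	lof_mechanism	chrom
ABCA4	established_IRD	AR	1	chr1
BBS2	established_syndromic	AR	1	chr16
C21orf2	established_syndromic	AR	1	chr21
C2orf71	established_IRD	AR	1	chr2
CEP290	established_syndromic	AR	1	chr12
CERKL	established_IRD	AR	1	chr2
CNGA3	established_IRD	AR	1	chr2
CNGB1	established_IRD	AR	1	chr16
CNGB3	established_IRD	AD,AR	1	chr8
CRB1	established_IRD	AR	1	chr1
CRX	established_IRD	AD	1	chr19
EYS	established_IRD	AR	1	chr6
GUCY2D	established_IRD	AD,AR	1	chr17
NRL	established_IRD	AD,AR	1	chr14
OPA1	established_IRD	AD	1	chr3
PDE6B	established_IRD	AD,AR	1	chr4
PHYH	established_syndromic	AR	1	chr10
PRPF31	established_IRD	AD	1	chr19
ROM1	established_IRD	AD,AR	1	chr11
RPGR	established_IRD	XL	1	chrX
UNC119	established_IRD	AD	1	chr17
USH2A	established_IRD	AR	1	chr1
CEP250	candidate_gene	AR	1	chr20
CEP78	candidate_gene	AR	1	chr9
SCLT1	candidate_gene	AR	1	chr4
SEMA6B	candidate_gene	AR	1	chr19
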