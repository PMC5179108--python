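# Cohort variant table: one row per classified allele (41 entries, 28 families with findings).
# Decimal commas of the published table are normalized to points; '.' marks a field not given.
# exac: 'AC/AN', 'Not present' (screened, absent) or 'Not Covered' (site not in the reference).
# coseg: yes | no | yes_unaffected_carriers (segregation showed unaffected carriers) | na (modifier rows)
family	section	secure	disease	gene	role	model	hgvs_c	hgvs_p	consequence	zygosity	coseg	pp2_call	pp2_score	sift_call	sift_score	mt_call	mt_score	cadd	exac	reported	functional_support	acmg_printed
A10	A	1	ar axial SMD	C21orf2	causal	AR_comphet	c.286G>A	p.E96K	missense	het	yes	Probably D.	1	Tolerated	.	Disease C.	1	36	Not present	novel	0	LikelyPathogenic
A10	A	1	ar axial SMD	C21orf2	causal	AR_comphet	c.631_632del	p.R211Hfs*46	frameshift	het	yes	.	.	.	.	Disease C.	1	.	Not present	novel	0	Pathogenic
64ORG	A	1	ar Refsum	PHYH	causal	AR_comphet	c.668C>G	p.P223R	missense	het	yes	Probably D.	1	Tolerated	0.06	Disease C.	1	22.7	Not present	novel	0	LikelyPathogenic
64ORG	A	1	ar Refsum	PHYH	causal	AR_comphet	c.683dupG	p.V229Sfs*2	frameshift	het	yes	.	.	.	.	Disease C.	1	.	2/121412	reported	0	Pathogenic
79ORG	A	1	arUSH	USH2A	causal	AR_comphet	c.2299delG	p.E767Sfs*21	frameshift	het	yes	.	.	.	.	.	.	.	96/121284	reported	0	Pathogenic
79ORG	A	1	arUSH	USH2A	causal	AR_comphet	c.9119G>A	p.W3040*	nonsense	het	yes	.	.	Tolerated	1	Disease C.	1	52	Not present	reported	0	Pathogenic
77ORG	B	0	arCD	ABCA4	causal	AR_comphet	c.3386G>T	p.R1129L	missense	het	yes	Probably D.	0.961	Damaging	0	Disease C.	1	28.01	30/121388	reported	0	LikelyPathogenic
77ORG	B	0	arCD	ABCA4	causal	AR_comphet	c.4539+2064C>T	.	deep_intronic	het	yes	.	.	.	.	Polymorphism	0	.	Not Covered	reported	0	VUS
A18	B	0	arRP	BBS2	causal	AR_hom	c.334T>C	p.F112L	missense	hom	yes	Probably D.	1	Damaging	0.01	Disease C.	1	28.8	1/121022	novel	0	VUS
55ORG	B	1	arCRD	C2orf71	causal	AR_hom	c.1067_1068del	p.N356Rfs*101	frameshift	hom	no	.	.	.	.	Disease C.	1	.	Not present	novel	0	Pathogenic
65ORG	B	0	arLCA	CEP290	causal	AR_comphet	c.148C>T	p.H50Y	missense	het	no	Possibly D.	0.952	Damaging	0.05	Disease C.	1	25	Not present	novel	0	VUS
65ORG	B	0	arLCA	CEP290	causal	AR_comphet	c.1322T>A	p.L441*	nonsense	het	no	.	.	Tolerated	1	Disease C.	1	41	Not present	novel	0	Pathogenic
67ORG	B	0	arRP	CERKL	causal	AR_hom	c.613+5_613+8del	.	noncanonical_splice_region	hom	yes	.	.	.	.	Disease C.	1	.	Not present	novel	0	VUS
75ORG	B	0	arAchr	CNGA3	causal	AR_hom	c.1768G>A	p.E590K	missense	hom	yes	Probably D.	0.954	Damaging	0.05	Disease C.	1	22.8	1/121004	reported	0	VUS
80ORG	B	1	arRP	CNGB1	causal	AR_hom	c.2762_2765delACGA	p.Y921Cfs*15	frameshift	hom	yes	.	.	.	.	.	.	.	Not present	novel	0	Pathogenic
71ORG	B	1	arAchr	CNGB3	causal	AR_hom	c.1148delC	p.T383Ifs*13	frameshift	hom	yes	.	.	.	.	Disease C.	1	.	224/120952	reported	0	Pathogenic
2ORG	B	1	arRP	CRB1	causal	AR_comphet	c.2688T>A	p.C896*	nonsense	het	no	.	.	Tolerated	1	Disease C.	1	23.2	2/121386	reported	0	Pathogenic
2ORG	B	1	arRP	CRB1	causal	AR_comphet	c.2842T>C	p.C948R	missense	het	no	Probably D.	0.996	Damaging	0	Disease C.	1	15.2	Not present	novel	0	LikelyPathogenic
10NCE	B	1	adRP	CRX	causal	AD	.	Deletion exons 3-4	exonic_deletion	het	yes	.	.	.	.	.	.	.	.	novel	0	Pathogenic
68ORG	B	1	arRP	EYS	causal	AR_comphet	c.2380C>T	p.R794*	nonsense	het	yes	.	.	.	.	Disease C.	1	37	1/19764	novel	0	Pathogenic
68ORG	B	1	arRP	EYS	causal	AR_comphet	.	Deletion 10 initial exons	exonic_deletion	het	yes	.	.	.	.	.	.	.	.	novel	0	Pathogenic
58ORG	B	1	arLCA	GUCY2D	causal	AR_hom	c.914delA	p.H305Pfs*90	frameshift	hom	yes	.	.	.	.	Disease C.	1	.	Not present	novel	0	Pathogenic
69ORG	B	1	arGF	NRL	causal	AR_hom	c.339C>G	p.Y113*	nonsense	hom	yes	.	.	.	.	Disease C.	1	37	Not present	novel	0	Pathogenic
81ORG	B	1	adOA	OPA1	causal	AD	c.800_801delAA	p.K267Rfs*4	frameshift	het	yes	.	.	.	.	.	.	.	1/120600	novel	0	Pathogenic
E4	B	1	adRP	PRPF31	causal	AD	.	Partial deletion & duplication	exonic_deletion	het	yes	.	.	.	.	.	.	.	.	novel	0	Pathogenic
76ORG	B	1	XlRP	RPGR	causal	XL	c.762_777delinsCA	p.T255Rfs*23	frameshift	hemi	yes	.	.	.	.	.	.	.	Not present	novel	0	Pathogenic
82ORG	B	1	adRP	UNC119	causal	AD	c.7delG	p.V3*	frameshift	het	no	.	.	.	.	.	.	.	Not present	novel	0	LikelyPathogenic
51ORG	B	1	arRP	USH2A	causal	AR_comphet	c.1724G>A	p.C575Y	missense	het	yes	Probably D.	1	Damaging	0	Disease C.	1	16.57	1/121370	reported	0	LikelyPathogenic
51ORG	B	1	arRP	USH2A	causal	AR_comphet	c.2276G>T	p.C759F	missense	het	yes	Probably D.	0.999	Damaging	0	Disease C.	1	23.1	95/121178	reported	0	LikelyPathogenic
73ORG	B	1	arRP	USH2A	causal	AR_comphet	c.2276G>T	p.C759F	missense	het	yes	Probably D.	0.999	Damaging	0	Disease C.	1	23.1	95/121178	reported	0	LikelyPathogenic
73ORG	B	1	arRP	USH2A	causal	AR_comphet	c.13010C>T	p.T4337M	missense	het	yes	Probably D.	0.986	Damaging	0	Disease C.	1	24.8	Not present	reported	0	LikelyPathogenic
22ORG	C	0	RP	CNGB3	causal	AD	c.1672G>T	p.G558C	missense	het	yes_unaffected_carriers	Probably D.	1	Damaging	0	Disease C.	1	26.8	4/119080	reported	0	VUS
22ORG	C	0	RP	CRB1	modifier	AD	c.1702C>T	p.H568Y	missense	het	na	Probably D.	0.997	Tolerated	1	Disease C.	1	16.43	Not present	reported	0	VUS
22ORG	C	0	RP	ROM1	modifier	AD	c.668G>A	p.R223Q	missense	het	na	Probably D.	0.999	Tolerated	0.09	Disease C.	1	36	17/121408	novel	0	VUS
39ORG	C	0	RP	PDE6B	causal	AD	c.928-9_940dup	p.Y314Cfs*50	frameshift	het	yes_unaffected_carriers	.	.	.	.	.	.	.	Not present	reported	0	Pathogenic
39ORG	C	0	RP	USH2A	modifier	AD	c.1246G>T	p.A416S	missense	het	na	Probably D.	0.998	Tolerated	0.1	Disease C.	1	24.5	1/117386	novel	0	VUS
A3	D	1	arRP	CEP250	causal	AR_hom	c.1826C>T	p.A609V	missense	hom	yes	Probably D.	.	Damaging	.	Neutral	.	20.6	33/121314	novel	1	LikelyPathogenic
56ORG	D	0	arRP	CEP78	causal	AR_hom	c.1056delT	p.T353Lfs*5	frameshift	hom	yes	.	.	.	.	Disease C.	1	.	Not present	novel	0	VGUS
62ORG	D	0	arRP	SCLT1	causal	AR_comphet	c.778-2A>T	.	canonical_splice	het	yes	.	.	.	.	Disease C.	1	19.45	Not present	novel	0	Pathogenic
62ORG	D	0	arRP	SCLT1	causal	AR_comphet	c.827G>A	p.R276H	missense	het	yes	Probably D.	0.998	.	.	Disease C.	1	20.6	3/121324	novel	0	VUS
66ORG	D	0	arCRD	SEMA6B	causal	AR_hom	c.493G>A	p.G165R	missense	hom	yes	Possibly D.	0.814	Damaging	0.03	Disease C.	0.995	14.13	1/118664	novel	0	VGUS
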