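case_id	phenotype	gene	transcript	variant	zygosity	inheritance	segregation
2	GDD	NIPBL	NM_133433.4	c.6056T>C p.(Leu2019Pro)	het	AD	N/A
5	ID	DLG4	NM_001321075.3	c.14_15delTG p.(Cys5Tyrfs*12)	het	AD	de novo
6	GDD	MED13L	NM_015335.5	c.700A>G, p.(Lys234Glu)	het	AD	de novo
16	ID	KCNA2	NM_004974.4	c.889C>T p.Arg297Trp	het	AD	de novo
17	ID	PPP2R1A	NM_014225.6	c.544C>T p.(Arg182Trp	het	AD	de novo
18	ID	SETD5	NM_001080517.3	c.2750delT p.(Leu917fs)	het	AD	de novo
23	GDD	PPP2R5D	NM_006245.4	c.592G>A p.(Glu198Lys)	het	AD	de novo
25	ASD	ZMYM2	NM_197968.4	c.3729_3730del p.(Phe1244*)	het	AD	pat
26	ID	ATP1A1	NM_000701.8	c.1181A>T p.(Asp394Val)	het	AD	de novo
27	ID	HNRNPK	NM_031263.4	c.1241G>A p.(Arg414His)	het	AD	de novo
30	ASD	MECP2	NM_001110792.2	c.952C>T p.(Arg318Cys)	het	AD	de novo
31	ID	MED13L	NM_015335.5	c.1768C>T p.(Gln590*)	het	AD	de novo
41	ID	CHD2	NM_001271.4	c.762_764del p.(Asp254del)	het	AD	de novo
42	ID	SCN8A	NM_001330260.2	c.2811G>A p.(Trp937*)	het	AD	de novo
43	ID	SCN8A	NM_001330260.2	c.2811G>A p.(Trp937*)	het	AD	de novo
44	ASD	GRIN2A	NM_001134407.3	c.395c>T p.(Ser132Phe)	het	AD	de novo
45	ASD	TCF12	NM_207037.2	c.686-1G>C	het	AD	de novo
50	ID	POU4F1	NM_006237.4	c.486_487insGG p.(Pro163Gly)	het	AD	de novo
54	ID	ANKRD11	NM_013275.6	c.1903_1907del (p.Lys635fs)	het	AD	de novo
55	GDD	PPP2R5D	NM_006245.4	c.592G>A p.(Glu198Lys)	het	AD	de novo
59	ID	SMARCA2	NM_003070.5	c.1574G>A p.(Arg525His)	het	AD	de novo
60	ASD	ASH1L	NM_018489.3	c.4579C>T p.(Arg1527*)	het	AD	de novo
63	ID	AUTS2	NM_015570.4	c.1603_1626del p.(His535-Thr542del)	het	AD	de novo
64	GDD	ITPR1	NM_001378452.1	c.1554+6T>G	het	AD	N/A
67	ASD	TRAPPC9	NM_001374682.1	c.307A>T p.(Lys103*)	het	AR	mat
67	ASD	TRAPPC9	NM_001374682.1	c. 610 C>T p.(Arg204Cys)	het	AR	pat
71	ID	SETBP1	NM_015559.3	c.1075C>T p.(Gln359Ter)	het	AD	de novo
74	GDD	SMC1A	NM_006306.4	c.170G>A p.(Arg57Gln)	het	XLD	de novo
77	GDD	KMT2A	NM_001197104.2	c.3853C>T p.(Gln1285*)	het	AD	de novo
79	ID	PRRT2	NM_145239.3	c.649del p.(Arg217GlufsTer12)	het	AD	de novo
80	ASD	SETD1A	NM_014712.3	c.644_645delinsCC p.(Glu215Ala)	het	AD	de novo
83	ID	CHD5	NM_015557.3	c.2842G>T p.(Val948Phe)	het	AD	N/A
84	GDD	CHD5	NM_015557.3	c.2842G>T p.(Val948Phe)	het	AD	N/A
85	ID	GRIA2	NM_001083619.3	c.857C>G p.(Pro286Arg)	het	AD	de novo
88	ID	SMARCD1	NM_003076.5	c.77C>T p.(Ala26Val)	het	AD	de novo
89	ID	ANKRD11	NM_013275.6	c.5806G>T p.(Glu1936*)	het	AD	de novo
91	GDD	KAT6A	NM_006766.5	c.3553C>T p.(Gln1185Ter)	het	AD	de novo
94	ID	PTEN	NM_000314.8	c.1003C>T p.(Arg335*)	het	AD	de novo
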