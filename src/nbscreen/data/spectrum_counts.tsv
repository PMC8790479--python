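disease	gene	transcript	count	variant_c	variant_p	classification
Primary carnitine deficiency	SLC22A5	NM_003060.4	9	c.1400C>G	p.S467C	P
Primary carnitine deficiency	SLC22A5	NM_003060.4	8	c.51C>G	p.F17L	VUS
Primary carnitine deficiency	SLC22A5	NM_003060.4	6	c.760C>T	p.R254X	P
Primary carnitine deficiency	SLC22A5	NM_003060.4	2	c.1195C>T	p.R399W	P
Primary carnitine deficiency	SLC22A5	NM_003060.4	2	c.338G>A	p.C113Y	P
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.1108G>A	p.G370R	VUS
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.1196G>A	p.R399Q	P
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.428C>T	p.P143L	LP
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.431T>C	p.L144P	VUS
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.470C>T	p.S157F	VUS
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.497+1G>T		P
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.621G>T	p.Q207H	LP
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.653-8T>A		VUS
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.782_799del	p.V261_P266del	VUS
Primary carnitine deficiency	SLC22A5	NM_003060.4	1	c.845G>A	p.R282Q	P
Hyperphenylalaninemia	PAH	NM_000277.3	3	c.158G>A	p.R53H	VUS
Hyperphenylalaninemia	PAH	NM_000277.3	2	c.1068C>A	p.Y356*	P
Hyperphenylalaninemia	PAH	NM_000277.3	2	c.498C>G	p.Y166*	P
Hyperphenylalaninemia	PAH	NM_000277.3	2	c.611A>G	p.Y204C	LP
Hyperphenylalaninemia	PAH	NM_000277.3	2	c.721C>T	p.R241C	P
Hyperphenylalaninemia	PAH	NM_000277.3	2	c.728G>A	p.R243Q	P
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.208_210delTCT	p.S70del	P
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.284_286del	p.I95del	P
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.331C>T	p.R111*	P
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.353-6T>C		P
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.464G>A	p.R155H	P
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.527G>A	p.R176Q	LP
Hyperphenylalaninemia	PAH	NM_000277.3	1	c.907del	p.S303Pfs*38	P
Hyperphenylalaninemia	PTS	NM_000317.3	1	c.4A>C	p.S2R	P
Hyperphenylalaninemia	PTS	NM_000317.3	1	c.259C>T	p.P87S	P
Hyperphenylalaninemia	PTS	NM_000317.3	1	c.84-291A>G		P
Hyperphenylalaninemia	PTS	NM_000317.3	1	c.286G>A	p.D96N	P
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	3	c.1031A>G	p.E344G	P
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	2	c.578C>T	p.S193L	VUS
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	2	c.413delA	p.N138Mfs*36	P
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	1	c.1130C>T	p.P377L	LP
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	1	c.795+1G>A		LP
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	1	c.758T>G	p.V253G	VUS
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	1	c.172C>T	p.R58*	LP
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	1	c.286G>A	p.G96S	LP
Short chain acyl CoA dehydrogenase deficiency	ACADS	NM_000017.4	1	c.220C>T	p.P74S	LP
Citrin deficiency	SLC25A13	NM_014251.2	4	c.852_855delTATG	p.M285Pfs*2	P
Citrin deficiency	SLC25A13	NM_014251.2	2	IVS16ins3kb	p.A584Vfs*2	P
Citrin deficiency	SLC25A13	NM_014251.2	1	c.1048G>A	p.D350N	VUS
Citrin deficiency	SLC25A13	NM_014251.2	1	c.1638_1660dup23	p.A554Gfs*17	P
Citrin deficiency	SLC25A13	NM_014251.2	1	c.1750_1751ins3kb		P
3-methylcrotonyl CoA carboxylase deficiency	MCCC2	NM_022132.4	1	c.1103delG	p.G368Vfs*70	LP
3-methylcrotonyl CoA carboxylase deficiency	MCCC2	NM_022132.4	1	c.1550G>A	p.G517E	VUS
3-methylcrotonyl CoA carboxylase deficiency	MCCC2	NM_022132.4	1	c.1061C>T	p.T354l	VUS
3-methylcrotonyl CoA carboxylase deficiency	MCCC2	NM_022132.4	1	c.1599T>A	p.D533E	VUS
3-methylcrotonyl CoA carboxylase deficiency	MCCC2	NM_022132.4	1	c.730C>G	p.P244A	VUS
3-methylcrotonyl CoA carboxylase deficiency	MCCC2	NM_022132.4	1	c.1144_1147inv	p.K382_K383delinsF*	P
Isovaleric acidemia	IVD	NM_002225.5	1	c.158G>C	p.Arg53Pro	P
Isovaleric acidemia	IVD	NM_002225.5	1	c.349G>A	p.Glu117Lys	VUS
Isovaleric acidemia	IVD	NM_002225.5	1	c.214G>A	p.D72N	VUS
Isovaleric acidemia	IVD	NM_002225.5	1	c.631A>G	p.T211A	LP
Isovaleric acidemia	IVD	NM_002225.5	1	c.865G>A	p.G289R	LP
Citrullinemia type I	ASS1	NM_000050.4	2	c.1087C>T	p.R363W	P
Citrullinemia type I	ASS1	NM_000050.4	1	c.748C>T	p.L250F	VUS
Citrullinemia type I	ASS1	NM_000050.4	1	c.11A>G	p.K4R	VUS
2-methylbutryl CoA dehydrogenase deficiency	ACADSB	NM_001609.3	3	c.1165A>G	p.M389V	P
Very long chain acyl CoA dehydrogenase deficiency	ACADVL	NM_000018.4	1	c.621_622+9del		P
Very long chain acyl CoA dehydrogenase deficiency	ACADVL	NM_000018.4	1	c.622+14del		VUS
Very long chain acyl CoA dehydrogenase deficiency	ACADVL	NM_000018.4	1	c.1531C>T	p.R511W	LP
Multiple acyl-CoA dehydrogenase deficiency	ETFB	NM_001985.2	1	c.340_342del	p.Lys114del	VUS
Multiple acyl-CoA dehydrogenase deficiency	ETFB	NM_001985.2	1	c.253C>T	p.Arg85Ter	P
Multiple acyl-CoA dehydrogenase deficiency	ETFB	NM_001985.2	1	c.82G>A	p.Gly28Ser	VUS
Hypermethioninemia	MAT1A	NM_000429.3	1	c.755T>C	p.I252T	LP
Hypermethioninemia	MAT1A	NM_000429.3	1	c.314A>T	p.N105I	VUS
Hypermethioninemia	MAT1A	NM_000429.3	1	c.386A>G	p.D129G	VUS
Glutaric acidemia type I	GCDH	NM_000159.3	1	c.532G>A	p.G178R	P
Glutaric acidemia type I	GCDH	NM_000159.3	1	c.1244-2A>C		P
Propionic acidemia	PCCA	NM_000282.4	1	c.819+1G>A		LP
Propionic acidemia	PCCA	NM_000282.4	1	c.1850T>C	p.L617P	VUS
Tyrosinemia type III	HPD	NM_002150.2	1	c.893A>C	p.Q298P	VUS
Tyrosinemia type III	HPD	NM_002150.2	1	c.217T>C	p.S73P	VUS
3-methylglutaconyl CoA hydratase deficiency	SERAC1	NM_032861.3	1	c.1364C>G	p.T455S	VUS
Nonketotic hyperglycinemia	GLDC	NM_000170.2	1	c.2405C>T	p.A802V	P
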