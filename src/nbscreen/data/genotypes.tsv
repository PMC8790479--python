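case_id	gene	transcript	allele1_c	allele1_p	allele2_c	allele2_p	allele3_c	allele3_p
A-1	PTS	NM_000317.3	c.84-291A>G		c.286G>A	p.D96N
A-2	PTS	NM_000317.3	c.4A>C	p.S2R	c.259C>T	p.P87S
A-3	PAH	NM_000277.3	c.611A>G	p.Y204C	c.158G>A	p.R53H
A-4	PAH	NM_000277.3	c.728G>A	p.R243Q	c.158G>A	p.R53H
A-5	PAH	NM_000277.3	c.721C>T	p.R241C
A-6	PAH	NM_000277.3	c.208_210delTCT	p.S70del	c.353-6T>C
A-7	PAH	NM_000277.3	c.1068C>A	p.Y356*	c.907del	p.S303Pfs*38
A-8	PAH	NM_000277.3	c.611A>G	p.Y204C	c.728G>A	p.R243Q
A-9	PAH	NM_000277.3	c.527G>A	p.R176Q	c.498C>G	p.Y166*
A-10	PAH	NM_000277.3	c.1068C>A	p.Y356*	c.158G>A	p.R53H
A-11	PAH	NM_000277.3	c.721C>T	p.R241C	c.284_286delTCA	p.I95del
A-12	PAH	NM_000277.3	c.464G>A	p.R155H	c.331C>T	p.R111*
A-13	MAT1A	NM_000429.3	c.755T>C	p.I252T
A-14	MAT1A	NM_000429.3	c.314A>T	p.N105I	c.386A>G	p.D129G
A-15	HPD	NM_002150.2	c.893A>C	p.Q298P	c.217T>C	p.S73P
A-16	ASS1	NM_000050.4	c.1087C>T	p.R363W	c.748C>T	p.L250F
A-17	ASS1	NM_000050.4	c.1087C>T	p.R363W	c.11A>G	p.K4R
A-18	SLC25A13	NM_014251.2	c.1048G>A	p.D350N	IVS16ins3kb	p.A584Vfs*2
A-19	SLC25A13	NM_014251.2	IVS16ins3kb	p.A584Vfs*2	c.852_855delTATG	p.M285Pfs*2
A-20	SLC25A13	NM_014251.2	c.852_855delTATG	p.M285Pfs*2
A-21	SLC25A13	NM_014251.2	c.852_855delTATG	p.M285Pfs*2	c.1638_1660dup23	p.A554Gfs*17
A-22	SLC25A13	NM_014251.2	c.852_855delTATG	p.M285Pfs*2	c.1750_1751ins3kb
O-1	MCCC2	NM_022132.4	c.730C>G	p.P244A	c.1144_1147inv	p.K382_K383delinsF*
O-2	MCCC2	NM_022132.4	c.1103delG	p.G368Vfs*70	c.1550G>A	p.G517E
O-3	MCCC2	NM_022132.4	c.1061C>T	p.T354l	c.1599T>A	p.D533E
O-4	ACADSB	NM_001609.3	c.1165A>G	p.M389V
O-5	ACADSB	NM_001609.3	c.1165A>G	p.M389V
O-6	ACADSB	NM_001609.3	c.1165A>G	p.M389V
O-7	PCCA	NM_000282.4	c.819+1G>A		c.1850T>C	p.L617P
O-8	GCDH	NM_000159.3	c.532G>A	p.G178R	c.1244-2A>C
O-9	IVD	NM_002225.5	c.158G>C	p.Arg53Pro	c.349G>A	p.Glu117Lys
O-10	IVD	NM_002225.5	c.631A>G	p.T211A	c.865G>A	p.G289R
F-1	SLC22A5	NM_003060.4	c.1400C>G	p.S467C	c.428C>T	p.P143L
F-2	SLC22A5	NM_003060.4	c.51C>G	p.F17L
F-3	SLC22A5	NM_003060.4	c.760C>T	p.R254X	c.1400C>G	p.S467C
F-4	SLC22A5	NM_003060.4	c.497+1G>T
F-5	SLC22A5	NM_003060.4	c.1400C>G	p.S467C
F-6	SLC22A5	NM_003060.4	c.51C>G	p.F17L	c.621G>T	p.Q207H
F-7	SLC22A5	NM_003060.4	c.431T>C	p.L144P	c.1195C>T	p.R399W
F-8	SLC22A5	NM_003060.4	c.51C>G	p.F17L	c.338G>A	p.C113Y
F-9	SLC22A5	NM_003060.4	c.1195C>T	p.R399W	c.1400C>G	p.S467C
F-10	SLC22A5	NM_003060.4	c.1400C>G	p.S467C	c.1196G>A	p.R399Q
F-11	SLC22A5	NM_003060.4	c.51C>G	p.F17L	c.470C>T	p.S157F
F-12	SLC22A5	NM_003060.4	c.338G>A	p.C113Y
F-13	SLC22A5	NM_003060.4	c.1108G>A	p.G370R	c.51C>G	p.F17L
F-14	SLC22A5	NM_003060.4	c.760C>T	p.R254X
F-15	SLC22A5	NM_003060.4	c.51C>G	p.F17L	c.782_799del	p.V261_P266del
F-16	SLC22A5	NM_003060.4	c.760C>T	p.R254X	c.845G>A	p.R282Q
F-17	SLC22A5	NM_003060.4	c.1400C>G	p.S467C
F-18	SLC22A5	NM_003060.4	c.760C>T	p.R254X	c.1400C>G	p.S467C
F-19	SLC22A5	NM_003060.4	c.760C>T	p.R254X	c.1400C>G	p.S467C
F-20	SLC22A5	NM_003060.4	c.51C>G	p.F17L	c.653-8T>A
F-21	SLC22A5	NM_003060.4	c.51C>G	p.F17L
F-22	SLC22A5	NM_003060.4	c.760C>T	p.R254X
F-23	ACADVL	NM_000018.4	c.621_622+9del		c.622+14del		c.1531C>T	p.R511W
F-24	ETFB	NM_001985.2	c.340_342del	p.Lys114del	c.253C>T	p.Arg85Ter	c.82G>A	p.Gly28Ser
F-25	ACADS	NM_000017.4	c.172C>T	p.R58*	c.286G>A	p.G96S
F-26	ACADS	NM_000017.4	c.220C>T	p.P74S	c.413del	p.N138Mfs*36
F-27	ACADS	NM_000017.4	c.1031A>G	p.E344G
F-28	ACADS	NM_000017.4	c.413delA	p.N138Mfs*36	c.758T>G	p.V253G
F-29	ACADS	NM_000017.4	c.1130C>T	p.P377L	c.578C>T	p.S193L
F-30	ACADS	NM_000017.4	c.795+1G>A		c.1031A>G	p.E344G
F-31	ACADS	NM_000017.4	c.578C>T	p.S193L	c.1031A>G	p.E344G
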