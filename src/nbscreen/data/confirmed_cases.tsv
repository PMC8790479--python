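workup	case_id	sex	age_days	diagnosis	gene	markers
laboratory	A-1	M	47	BH4D	PTS	PHE=444.79
laboratory	A-2	M	41	BH4D	PTS	PHE=245.11
laboratory	A-3	M	30	PAHD	PAH	PHE=105.43
laboratory	A-4	F	47	PAHD	PAH	PHE=132.91
laboratory	A-5	M	33	PAHD	PAH	PHE=218.86
laboratory	A-6	M	50	PAHD	PAH	PHE=745.62
laboratory	A-7	F	36	PAHD	PAH	PHE=562.35
laboratory	A-8	M	31	PAHD	PAH	PHE=502.76
laboratory	A-9	F	30	PAHD	PAH	PHE=159.60
laboratory	A-10	M	19	PAHD	PAH	PHE=135.63
laboratory	A-11	F	34	PAHD	PAH	PHE=264.59
laboratory	A-12	F	27	PAHD	PAH	PHE=160.25
laboratory	A-13	F	35	H-MET	MAT1A	MET=46.97
laboratory	A-14	F	27	H-MET	MAT1A	MET=75.66
laboratory	A-15	M	33	TYR-III	HPD	TYR=447.22
laboratory	A-16	F	54	CIT-I	ASS1	CIT=350.67
laboratory	A-17	M	77	CIT-I	ASS1	CIT=39.00
laboratory	A-18	F	21	CD	SLC25A13	CIT=186.21
laboratory	A-19	M	25	CD	SLC25A13	CIT=72.41
laboratory	A-20	M	50	CD	SLC25A13	CIT=92.49
laboratory	A-21	M	43	CD	SLC25A13	CIT=40.68
laboratory	A-22	F	40	CD	SLC25A13	CIT=25.83
laboratory	O-1	M	23	3-MCCD	MCCC2	C4DC + C5OH=0.83
laboratory	O-2	M	30	3-MCCD	MCCC2	C4DC + C5OH=1.13
laboratory	O-3	M	78	3-MCCD	MCCC2	C4DC + C5OH=3.5
laboratory	O-4	M	31	2-MBDD	ACADSB	C5=0.43
laboratory	O-5	M	41	2-MBDD	ACADSB	C5=0.48
laboratory	O-6	M	41	2-MBDD	ACADSB	C5=0.83
laboratory	O-7	M	33	PA	PCCA	C3=4.28
laboratory	O-8	F	16	GA-I	GCDH	C5DC + C6OH=2.49
laboratory	O-9	F	16	IVA	IVD	C5=9.12
laboratory	O-10	F	34	IVA	IVD	C5=1.41
laboratory	F-1	M	35	PCD	SLC22A5	C0=5.15
laboratory	F-2	M	17	PCD	SLC22A5	C0=4.36
laboratory	F-3	M	19	PCD	SLC22A5	C0=4.23
laboratory	F-4	F	23	PCD	SLC22A5	C0=2.79
laboratory	F-5	F	36	PCD	SLC22A5	C0=6.13
laboratory	F-6	F	23	PCD	SLC22A5	C0=5.24
laboratory	F-7	F	40	PCD	SLC22A5	C0=5.11
laboratory	F-8	M	28	PCD	SLC22A5	C0=5.19
laboratory	F-9	M	59	PCD	SLC22A5	C0=5.28
laboratory	F-10	M	33	PCD	SLC22A5	C0=7.54
laboratory	F-11	M	154	PCD	SLC22A5	C0=4.39
laboratory	F-12	M	31	PCD	SLC22A5	C0=1.94
laboratory	F-13	F	22	PCD	SLC22A5	C0=2.47
laboratory	F-14	F	38	PCD	SLC22A5	C0=2.97
laboratory	F-15	M	51	PCD	SLC22A5	C0=5.18
laboratory	F-16	F	38	PCD	SLC22A5	C0=4.94
laboratory	F-17	F	46	PCD	SLC22A5	C0=6.72
laboratory	F-18	F	23	PCD	SLC22A5	C0=3.52
laboratory	F-19	M	37	PCD	SLC22A5	C0=4.88
laboratory	F-20	M	25	PCD	SLC22A5	C0=3.08
laboratory	F-21	M	56	PCD	SLC22A5	C0=4.99
laboratory	F-22	F	56	PCD	SLC22A5	C0=3.25
laboratory	F-23	F	31	VLCADD	ACADVL	C12=0.66;C14=2.76;C18=2.23
laboratory	F-24	M	53	MADD	ETFB	C5=0.45;(C5DC + C6OH)/(C3DC + C4OH)=5.0
laboratory	F-25	M	41	SCADD	ACADS	C4=1.46
laboratory	F-26	M	26	SCADD	ACADS	C4=1.20
laboratory	F-27	M	38	SCADD	ACADS	C4=1.41
laboratory	F-28	M	49	SCADD	ACADS	C4=1.83
laboratory	F-29	M	59	SCADD	ACADS	C4=0.91
laboratory	F-30	M	30	SCADD	ACADS	C4=1.75
laboratory	F-31	F	140	SCADD	ACADS	C4=1.61
clinical	C-1	M	40	HPA		PHE=701.03
clinical	C-2	M	60	HPA		PHE=563.53
clinical	C-3	F	75	HPA		PHE=498.89
clinical	C-4	M	42	HPA		PHE=148.76
clinical	C-5	M	56	HPA		PHE=269.3
clinical	C-6	F	50	HPA		PHE=172.9
clinical	C-7	M	20	PA		C3=10.45
clinical	C-8	M		PA		C3=17.89
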