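disorder	abbrev	category	cases
Phenylalanine hydroxylase deficiency	PAHD	AAMD	16
Tetrahydrobiopterin deficiency	BH4D	AAMD	2
Citrullinemia type I	CIT-I	AAMD	2
Citrin deficiency	CD	AAMD	5
Hypermethioninemia	H-MET	AAMD	2
Tyrosinemia type III	TYR-III	AAMD	1
Isovaleric acidemia	IVA	OAMD	2
Glutaric acidemia type I	GA-I	OAMD	1
Propionic acidemia	PA	OAMD	3
2-methylbutyryl-CoA dehydrogenase deficiency	2-MBDD	OAMD	3
3-methylcrotonyl-CoA carboxylase deficiency	3-MCCD	OAMD	3
Primary carnitine deficiency	PCD	FAOD	22
Short-chain acyl-CoA dehydrogenase deficiency	SCADD	FAOD	7
Very-long-chain acyl-CoA dehydrogenase deficiency	VLCADD	FAOD	1
Multiple acyl-CoA dehydrogenase deficiency	MADD	FAOD	1
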