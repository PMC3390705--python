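rsid	chromosome	position	functional_type	adjacent_gene	is_esnp
rs7578597	2		missense	THADA	1
rs4402960	3		intron	IGF2BP2	1
rs1470579	3		intron	IGF2BP2	1
rs4607103	3		intergenic		1
rs10010131	4		intron	WFS1	1
rs7754840	6		intron	CDKAL1	0
rs7756992	6		intron	CDKAL1	0
rs10946398	6		intron	CDKAL1	0
rs4712523	6		intron	CDKAL1	0
rs864745	7		intron	JAZF1	1
rs13266634	8		missense	SLC30A8	1
rs10811661	9		intergenic		0
rs564398	9		intergenic		1
rs7903146	10		intron	TCF7L2	1
rs12255372	10		intron	TCF7L2	1
rs7901695	10		intron	TCF7L2	1
rs11196205	10		intron	TCF7L2	1
rs7895340	10		intron	TCF7L2	1
rs4506565	10		intron	TCF7L2	1
rs1111875	10		intergenic	HHEX	1
rs5015480	10		intergenic	HHEX	1
rs12779790	10		intergenic		1
rs5219	11		missense	KCNJ11	0
rs2237892	11		intron	KCNQ1	1
rs2237895	11		intron	KCNQ1	0
rs2237897	11		intron	KCNQ1	1
rs10830963	11		intron	MTNR1B	0
rs7961581	12		intergenic		1
rs8050136	16		intron	FTO	0
rs9939609	16		intron	FTO	0
rs4430796	17		intron	HNF1B	0
rs1884613	20		intergenic		0
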