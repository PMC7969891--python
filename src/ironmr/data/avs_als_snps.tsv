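rsid	effect_allele	other_allele	eaf	beta	se	pvalue
rs1800562	A	G	0.062	0.02	0.03	0.45
rs1799945	C	G	0.849	0.01	0.02	0.64
rs855791	A	G	0.433	-0.01	0.01	0.33
rs744653	T	C	0.859	-0.02	0.02	0.39
rs8177240	T	G	0.664	0.02	0.01	0.16
rs9990333	T	C	0.459	0.00	0.01	0.75
rs7385804	A	C	0.634	0.03	0.01	0.06
rs4921915	A	G	0.773	-0.01	0.02	0.63
rs651007	T	C	0.215	0.03	0.02	0.05
rs6486121	T	C	0.522	0.00	0.01	0.79
rs174577	A	C	0.340	-0.00	0.01	0.94
rs411988	A	G	0.510	-0.02	0.01	0.23
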