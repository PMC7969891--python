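chrom	rsid	pos	effect_allele	other_allele	eaf	iron_beta	iron_se	ferritin_beta	ferritin_se	transferrin_saturation_beta	transferrin_saturation_se	transferrin_beta	transferrin_se
6	rs1799945	26091179	C	G	0.85	-0.19	0.01	-0.07	0.01	-0.23	0.01	0.11	0.01
6	rs1800562	26093141	A	G	0.07	0.33	0.02	0.20	0.02	0.58	0.02	-0.48	0.02
22	rs855791	37462936	A	G	0.45	-0.18	0.01	-0.06	0.01	-0.19	0.01	0.04	0.01
3	rs8177240	133477701	T	G	0.67	-0.07	0.01			0.10	0.01	-0.38	0.01
7	rs7385804	100235970	A	C	0.62	0.06	0.01			0.05	0.01
9	rs651007	136153875	T	C	0.20			-0.05	0.01
17	rs411988	56709034	A	G	0.46			-0.04	0.01
2	rs744653	190378750	T	C	0.85			-0.09	0.01			0.07	0.01
3	rs9990333	195827205	T	C	0.46							0.06	0.01
8	rs4921915	18272466	A	G	0.78							0.08	0.01
11	rs6486121	13355770	T	C	0.63							-0.05	0.01
11	rs174577	61604814	A	C	0.33							0.06	0.01
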