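snp	chr	pos	reported_trait	gene	category	gwas_beta	gwas_a1	gwas_p	a2	a1	maf	beta	se	permutation_p
rs12855	1	50974421	Thyroid-stimulating hormone	CDKN2C	thyroid	0.033	T	3e-13	C	T	0.144	2.236	1.07	3.90e-02
rs622474	1	66277601	Thyroid-stimulating hormone	PDE4B	thyroid	0.02	A	8e-15	A	G	0.483	1.692	0.759	2.70e-02
rs11204752	1	150985657	Thyroid-stimulating hormone	GOLPH3L	thyroid	0.017	T	2e-10	C	T	0.367	1.782	0.816	3.08e-02
rs6722076	2	233738671	Thyroxine	UGT1A6	thyroid	-0.104	A	6e-10	G	A	0.15	2.621	1.044	1.30e-02
rs6717283	2	241576690	Thyroid-stimulating hormone	BOK	thyroid	0.046	G	1e-11	A	G	0.078	3.888	1.528	1.41e-02
rs16874919	4	24063586	Thyroid-stimulating hormone	PPARGC1A	thyroid	0.025	A	2e-17	G	A	0.283	-2.095	1.006	3.85e-02
rs6462411	7	3875932	Thyroid-stimulating hormone	SDK1	thyroid	-0.36	C	1e-06	T	C	0.156	-2.456	1.135	3.51e-02
rs59282311	8	65974221	Thyroid-stimulating hormone	PDE7A	thyroid	-0.019	A	1e-12	A	G	0.111	2.538	1.263	4.81e-02
rs1441198	8	69506886	Thyroid-stimulating hormone	SULF1	thyroid	0.018	A	1e-11	A	G	0.1	-3.092	1.361	2.63e-02
rs9298749	9	16214342	Thyroid-stimulating hormone	BNC2	thyroid	-0.038	A	6e-11	C	A	0.35	1.874	0.831	2.54e-02
rs925489	9	97784318	Thyroid-stimulating hormone	TRMO	thyroid	-0.058	C	1e-13	T	C	0.044	3.787	1.769	3.41e-02
rs7855088	9	97979971	Thyroid-stimulating hormone	ANP32B	thyroid	-0.05	C	6e-06	C	T	0.339	2.249	1.018	2.77e-02
rs657152	9	133263862	Thyroid-stimulating hormone	ABO	thyroid	0.058	A	4e-10	C	A	0.422	-1.747	0.795	2.93e-02
rs7020640	9	136653172	Triiodothyronine	EGFL7	thyroid	0.026	T	9e-07	C	T	0.083	4.245	1.338	2.80e-03
rs6499766	16	55570216	Thyroxine	LPCAT2	thyroid	0.056	A	1e-06	T	A	0.328	1.847	0.808	2.27e-02
rs7253430	19	1803583	Thyroid-stimulating hormone	ATP8B3	thyroid	0.02	A	7e-06	G	T	0.272	-2.112	0.965	3.93e-02
rs1354034	3	56815721	Cold-inducible RNA-binding protein measurement	ARHGEF3	cold_heat	-0.183	T	4e-46	C	T	0.444	2.008	0.757	1.80e-03
rs17122904	1	62006470	Cold-induced vasodilation	PATJ	cold_heat			8e-06	A	G	0.406	-1.679	0.831	4.87e-02
rs77101060	10	106633287	Cold sensitivity	SORCS1	cold_heat	-0.96	T	6.45e-06	C	T	0.261	1.948	0.913	3.54e-02
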