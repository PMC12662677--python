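snp	chr	pos	reported_trait	gene	category	gwas_beta	gwas_a1	gwas_p	a2	a1	maf	beta	se	permutation_p
rs12409301	1	19448221	Thyroid-stimulating hormone	CAPZB	thyroid	-0.053	A	3e-78	G	A	0.283	2.312	0.976	2.05e-02
rs12855	1	50974421	Thyroid-stimulating hormone	CDKN2C	thyroid	0.033	T	3e-13	C	T	0.144	-2.256	1.091	4.20e-02
rs951366	1	205716224	Thyroxine	PM20D1	thyroid	0.037	T	6e-08	T	C	0.272	-2.74	1.004	7.20e-03
rs59381142	3	194198392	Thyroid-stimulating hormone	HES1	thyroid	-0.049	A	3e-53	G	A	0.311	1.9	0.874	3.48e-02
rs11755845	6	43937043	Thyroid-stimulating hormone	VEGFA	thyroid	-0.065	T	2e-10	C	T	0.117	-2.5	1.223	4.45e-02
rs10814915	9	4290544	Thyroid-stimulating hormone	GLIS3	thyroid	0.053	T	1e-95	C	T	0.439	-1.772	0.767	2.29e-02
rs7045138	9	97829181	Thyroxine	TRMO	thyroid	0.098	T	2e-11	T	C	0.122	-3.221	1.24	1.19e-02
rs11255790	10	8640217	Thyroid-stimulating hormone	NA	thyroid	-0.027	T	4e-21	C	T	0.128	3.594	1.159	3.10e-03
rs10905868	10	10932293	Thyroid-stimulating hormone	CELF2	thyroid	0.02	G	4e-06	A	G	0.094	3.743	1.334	6.70e-03
rs4933466	10	88089762	Thyroid-stimulating hormone	PTEN	thyroid	0.028	A	2e-26	G	A	0.222	-2.149	1.018	4.30e-02
rs2475217	10	103914337	Triiodothyronine	SLK	thyroid	0.019	C	3e-06	C	T	0.011	8.125	3.785	3.37e-02
rs643506	11	111765903	Thyroid-stimulating hormone	PPP2R1B	thyroid	-0.021	T	6e-14	G	T	0.178	2.443	1.11	2.64e-02
rs71430783	14	93092108	Thyroid-stimulating hormone	ITPK1	thyroid	0.069	T	2e-110	G	T	0.089	2.791	1.391	4.70e-02
rs2601803	16	4095640	Thyroid-stimulating hormone	ADCY9	thyroid	-0.028	C	4e-13	C	G	0.433	2.489	0.873	7.10e-03
rs3848445	17	14390704	Triiodothyronine	HS3ST3B1	thyroid			8e-09	T	C	0.361	-2.317	0.789	4.20e-03
rs75261749	17	51582013	Thyroid-stimulating hormone	UTP18	thyroid	-1.421	A	9e-24	G	A	0.033	7.106	2.193	2.40e-03
rs9915657	17	72131395	Thyroid-stimulating hormone	SOX9	thyroid	-0.064	T	8e-13	C	T	0.239	2.425	0.947	1.30e-02
rs4552110	18	59516716	Thyroid-stimulating hormone	CCBE1	thyroid	-0.0303	A	1e-19	A	T	0.0555	-4.167	1.803	2.12e-02
rs62143197	19	53817462	Cold-inducible RNA-binding protein measurement	NLRP12	cold_heat	0.66	A	4e-120	G	A	0.133	-2.943	1.431	4.31e-02
rs4666462	2	19117243	Response to cold	OSR1	cold_heat			2e-06	A	G	0.133	2.606	1.271	4.45e-02
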