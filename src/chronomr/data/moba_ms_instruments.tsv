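epoch	snp_id	gene	effect_allele	other_allele	eaf	beta_exp	se_exp	pval_exp	beta_out	se_out	pval_out
birth	rs11187129	HHEX	T	C	0.54108	-0.0471726	0.008338	2.10E-08	0.094401	0.01739	5.68E-08
birth	rs11708067	ADCY5	A	G	0.765083	-0.0789424	0.009755	5.20E-16	-1.00E-04	0.029553	0.9973
birth	rs1482853	CCNL1	C	A	0.598464	0.0988178	0.008435	5.90E-32	-0.01511	0.016958	0.3728
birth	rs2298615	EHBP1L1	C	T	0.76651	-0.0712846	0.012196	5.40E-09	0.045929	0.02142	0.03202
birth	rs28642213	GPSM1	A	G	0.267403	0.0623516	0.009521	4.70E-11	0.02245	0.028404	0.4293
birth	rs7310615	SH2B3	C	G	0.45479	-0.0498278	0.008508	6.50E-09	0.067752	0.016702	4.98E-05
birth	rs739669	DLG4	G	A	0.376996	-0.0715704	0.008601	4.70E-17	-0.02358	0.01775	0.1841
birth	rs7772579	ESR1	A	C	0.699604	0.0651087	0.009067	5.90E-13	0.002297	0.018227	0.8997
infancy	rs1032296	HHIP	T	C	0.376232	0.0524932	0.009097	1.10E-08	0.025831	0.017131	0.1316
infancy	rs10493544	TNNI3K	T	C	0.430744	0.0538075	0.009404	7.10E-09	-0.00638	0.01639	0.6971
infancy	rs11676272	ADCY3	A	G	0.51411	-0.0887022	0.009299	2.80E-22	-0.0203	0.016619	0.2218
infancy	rs13038017	EFCAB8	T	C	0.47431	-0.0535926	0.009372	1.20E-08	0.001601	0.016545	0.9229
infancy	rs17145750	MLXIPL	C	T	0.840536	0.0697872	0.011991	6.80E-09	-0.02706	0.025971	0.2974
infancy	rs1772945	OPRM1	G	A	0.441547	-0.0562618	0.00938	3.20E-09	-0.0031	0.016224	0.8487
infancy	rs1820721	GLPR1	C	A	0.511425	-0.0607290	0.008743	7.20E-12	0.016333	0.016275	0.3156
infancy	rs1985927	SCGB1A1	T	C	0.270127	-0.0597242	0.010637	6.80E-09	-0.0244	0.019192	0.2036
infancy	rs209421	UBE3D	G	T	0.264271	0.0727381	0.009951	5.40E-13	0.006521	0.018044	0.7178
infancy	rs2585058	SH3GL3	G	A	0.525095	0.0630845	0.009321	8.60E-12	0.007373	0.016718	0.6592
infancy	rs2728641	RP11-405A12.2	C	T	0.477989	0.0501517	0.008951	1.90E-08	0.0244	0.016829	0.1471
infancy	rs2767486	LEPR	A	G	0.838584	-0.14325	0.011859	6.40E-34	-0.03816	0.021062	0.07
infancy	rs2816985	NR5A2	A	G	0.551004	-0.0591627	0.009057	5.40E-11	-0.02762	0.016419	0.09259
infancy	rs28457693	PTCH1	A	G	0.865473	-0.0726875	0.01297	2.40E-08	-0.03449	0.029121	0.2363
infancy	rs287621	KLF14	T	C	0.260505	0.0636843	0.010075	3.70E-10	-0.0141	0.018164	0.4376
infancy	rs3741508	NCOR2	T	G	0.856761	0.0826905	0.013414	1.20E-09	0.009356	0.025142	0.7098
infancy	rs6538845	RP11-690J15.1	T	C	0.515215	-0.0549436	0.008957	1.50E-09	-0.02567	0.016303	0.1154
infancy	rs6899303	PCSK1	A	C	0.368755	-0.057154	0.009025	5.30E-11	-0.00409	0.016591	0.8052
early_childhood	rs11676272	ADCY3	A	G	0.515086	-0.0750482	0.010748	2.70E-12	-0.0203	0.016619	0.2218
early_childhood	rs12672489	KLF14	C	T	0.745792	0.0726685	0.012849	1.10E-08	0.015775	0.018633	0.3972
early_childhood	rs1830890	PLCE1	A	G	0.678614	-0.0665976	0.011646	1.30E-08	-0.00733	0.017525	0.6759
early_childhood	rs2767486	LEPR	A	G	0.837712	-0.0853349	0.014622	4.60E-09	-0.03816	0.021062	0.07
later_childhood	rs10493544	TNNI3K	T	C	0.43154	0.0651591	0.01198	4.80E-08	-0.00638	0.01639	0.6971
later_childhood	rs11676272	ADCY3	A	G	0.515866	-0.078168	0.013323	2.90E-09	-0.0203	0.016619	0.2218
later_childhood	rs17817288	FTO	A	G	0.513158	-0.0952937	0.013447	1.30E-12	-0.03325	0.016187	0.03999
later_childhood	rs545608	SEC16B	G	C	0.766209	-0.0877785	0.015795	3.20E-08	-0.01114	0.020384	0.5848
later_childhood	rs7132908	FAIM2	G	A	0.598895	-0.0813492	0.01358	3.30E-09	-0.03999	0.016912	0.01805
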