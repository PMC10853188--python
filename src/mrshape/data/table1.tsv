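rsid	groups	chrom	pos	gene	effect_allele	other_allele	eaf	maf	beta	se	pvalue	f_printed	cadd	r2_iv_a	partner_rsid
rs1868602	IV_A	3	132913122	TMEM108	T	C	0.274	0.289	0.0567	0.0113	5.29e-7	25.2	2.14
rs13151695	IV_A	4	106420356	EEF1A1P9	C	T	0.290	0.275	-0.0569	0.0116	8.87e-7	24.1	2.91
rs115656533	IV_A	5	79405179	SERINC5	T	A	0.164	0.166	-0.0693	0.0151	4.24e-6	21.1	0.79
rs6873320	IV_A	5	79528084	SERINC5	A	G	0.353	0.393	-0.0551	0.0114	1.31e-6	23.4	0.85
rs7450600	IV_A	6	166403646	LINC00473	C	T	0.103	0.085	-0.0837	0.0168	6.76e-7	24.8	2.92
rs140738399	IV_A	9	85317761	RPS6P12	G	A	0.053	0.066	0.1182	0.0248	1.91e-6	22.7	1.71
rs142967045	IV_A	10	118797350	KIAA1598	T	C	0.030	0.022	-0.1202	0.0258	3.12e-6	21.7	0.77
rs11620763	IV_A;IV_B	14	94768392	SERPINA6	A	G	0.193	0.197	-0.0858	0.0135	1.97e-10	40.4	0.34
rs9989237	IV_A;IV_B	14	94795202	SERPINA6	T	C	0.210	0.205	0.0857	0.0095	2.16e-19	81.4	0.57
rs7161231	IV_A	14	94808760	SERPINA6	T	C	0.101	0.105	0.0677	0.0129	1.71e-7	27.5	5.86
rs9996658	IV_replacement	4	106415560	EEF1A1P9	A	C	0.292	0.275	-0.0511	0.0111	4.29e-6	21.2	7.24	1.000	rs13151695
rs7141205	IV_replacement	14	94768859	SERPINA6	G	A	0.195	0.197	-0.0612	0.0102	1.68e-9	36.0	1.82	1.000	rs11620763
rs6776118	IV_high_CADD	3	132947776	TMEM108	T	A	0.260	0.259	0.0524	0.0113	3.52e-6	21.5	12.42	0.748	rs1868602
rs13104830	IV_high_CADD	4	106389297	PPA2	T	C	0.296	0.286	-0.0456	0.0110	3.23e-5	17.2	12.91	0.946	rs13151695
rs480621	IV_high_CADD	6	166419693	LINC00473	T	G	0.101	0.084	-0.0781	0.0169	3.69e-6	21.4	19.53	0.901	rs7450600
rs7146221	IV_B	14	94769081	SERPINA6	A	G	0.454	0.456	-0.0504	0.0082	6.28e-10	37.8	1.23
rs2736898	IV_B	14	94823817	SERPINA2P	T	C	0.497	0.491	0.0585	0.0078	7.03e-14	56.3	4.00
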