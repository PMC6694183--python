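trait	ko	gene	mean_abundance	pls_estimate	vip	cluster
FCR	K03783	punA	0.0107	-0.2755	1.22	NA
FCR	K08138	xylE	0.0404	0.1135	1.09	05
FCR	K00046	idnO	0.0845	0.0166	1.08	11
FCR	K00040	uxuB	0.0847	0.0503	1.01	25
FCR	K01759	glo1	0.0021	0.1547	1.01	09
FCR	K00849	galK	0.0631	0.0675	1.00	05
FCR	K01195	uidA	0.0127	-0.1174	0.99	07
FCR	K14220	tRNA-Asn	0.0155	0.0139	0.96	NC
FCR	K00677	lpxA	0.0403	-0.0186	0.91	25
FCR	K01188	beta-glucosidase	0.0398	-0.0210	0.90	NA
FCR	K07214	fes	0.0475	-0.1511	0.90	NA
FCR	K03303	lctP	0.0195	-0.0271	0.88	28
FCR	K00634	ptb	0.0075	-0.0079	0.85	NA
FCR	K01235	aguA	0.0104	-0.0626	0.80	NC
FCR	K07561	dph2	0.0030	-0.3881	1.86	01
FCR	K01925	murD	0.0620	-0.0857	0.99	NA
FCR	K02437	gcvH	0.0069	-0.0167	0.93	NA
FCR	K03530	hupB	0.0331	-0.0892	0.89	19
FCR	K02600	nusA	0.1126	-0.0655	0.89	NA
FCR	K02518	infA	0.0346	0.0170	0.88	21
ADG	K01448	amiABC	0.0236	-0.1937	1.22	06
ADG	K00133	asd	0.1197	-0.0684	1.20	NC
ADG	K01912	paaK	0.1543	-0.0980	1.16	16
ADG	K02919	rpmJ	0.0261	-0.1884	1.04	NC
ADG	K02879	rplQ	0.0773	0.0746	1.00	21
ADG	K02113	atpH	0.0292	-0.0486	1.00	21
ADG	K00283	gcvPB	0.0284	0.0502	0.99	25
ADG	K03775	slyD	0.0139	0.0672	0.93	22
ADG	K07561	dph2	0.0030	0.2310	1.20	01
ADG	K01925	murD	0.0620	0.1155	1.15	NA
ADG	K02437	gcvH	0.0069	0.1209	1.08	NA
ADG	K03530	hupB	0.0331	0.1062	1.07	19
ADG	K02600	nusA	0.1126	0.0726	1.02	NA
ADG	K02518	infA	0.0346	0.0646	0.98	21
RFI	K03406	mcp	0.0225	-0.0510	1.26	NA
RFI	K03413	cheY	0.0018	0.0478	1.16	NA
RFI	K01534	zntA	0.0211	-0.0653	1.16	04
RFI	K07258	dacC	0.0049	-0.0375	1.14	NA
RFI	K07301	yrbG	0.0096	-0.0145	1.09	04
RFI	K04720	cobD	0.0034	-0.0501	1.06	04
RFI	K03407	cheA	0.0048	-0.0236	1.04	NA
RFI	K00595	cobL	0.0078	0.0223	1.02	04
RFI	K01571	oadA	0.0165	-0.0501	0.96	04
RFI	K02057	ABC.SS.P	0.0023	-0.1375	0.96	20
RFI	K02390	flgE	0.0015	-0.0376	0.87	NA
RFI	K02417	fliN	0.0018	-0.1120	0.77	NA
RFI	K03738	aor	0.0144	-0.0657	0.68	NC
RFI	K02009	cbiN	0.0074	-0.1126	0.67	01
RFI	K01709	rfbG	0.0041	0.2549	1.46	NA
RFI	K00978	rfbF	0.0042	0.2056	1.23	NA
RFI	K14113	ehbD	0.0010	0.1703	1.00	NC
DFI	K00370	narG	0.0022	-0.2272	1.22	NA
DFI	K01858	INO1	0.0542	-0.0459	1.14	NA
DFI	K03685	rnc	0.0288	-0.0097	1.13	NA
DFI	K00613	GATM	0.0019	-0.1417	1.09	NA
DFI	K02428	rdgB	0.0147	-0.0216	0.94	02
DFI	K03602	xseB	0.0035	0.0803	0.94	02
DFI	K03210	yajC	0.0069	0.1317	0.93	NA
DFI	K12340	tolC	0.0157	0.0068	0.92	02
DFI	K03043	rpoB	1.2470	-0.0995	0.91	NC
DFI	K04751	glnB	0.0151	0.0613	0.91	02
DFI	K03625	nusB	0.0135	0.0766	0.91	02
DFI	K06178	rluB	0.0693	-0.0038	0.85	02
DFI	K05349	bglX	0.2272	0.0063	0.84	NA
DFI	K05515	mrdA	0.0295	0.0214	0.82	02
DFI	K04764	ihfA	0.0041	0.0306	0.80	02
DFI	K01709	rfbG	0.0041	0.2412	1.53	NA
DFI	K00978	rfbF	0.0042	0.2634	1.43	NA
DFI	K14113	ehbD	0.0010	0.1594	1.16	NC
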