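chrom	locus	start	end	line1_density	gene	break_frequency
1	p34.2	41313735	41355091	58.03	SCMH1	10.4
1	p34.2	41479154	41520306	21.87		11.9
1	p31.3	63102450	63125693	25.81		9.0
1	q21.1	145031426	145108225	54.69	PRKAB2	6.0
2	p23.2	27659776	28122129	48.23	BRE	6.0
2	p15	63302135	63367996	65.29	C2orf86	9.0
2	p11.2	88925032	88984458	53.85		6.0
2	q11.2	96394039	96423431	47.63		13.4
2	q14.2	118022882	119843354	27.52	DBI	7.5
3	p24.2	25637260	25664255	25.93	TOP2B	16.4
3	p24.2	25799317	25810811	8.7	OXSM	10.4
3	p24.2	25810870	25997134	29.53		10.4
3	q11.2	90336752	95063426	1.23		6.0
3	q26.1	163874118	163997228	33.3		47.8
4	q23	99907678	100011201	56.99		6.0
4	q31.3	152038958	152092912	48.19	LRBA	7.5
4	q31.3	153097317	153228047	17.59		7.5
4	q34.1	174459916	174490317	23.03	HMGB2	6.0
5	q13.3	75888651	75947525	25.48	IQGAP2, F2RL2	7.5
5	q13.3	76284777	76301015	0.0	CRHBP	7.5
5	q31.3	140094857	140166875	59.71	PCDHA1/2/3	7.5
5	q33.3	157216334	157301114	41.28		9.0
5	q34	162798715	162800093	0.0	CCNG1	9.0
5	q34	162818326	162833628	19.61	HMMR	11.9
5	q35.1	170161782	170195254	8.96		7.5
5	q35.1	170596026	170659586	33.04	RANBP17	6.0
6	q11.1	62760108	62854732	38.05	KHDRBS2	9.0
6	q26	162822332	162896532	9.43	PARK2	7.5
6	q27	166369554	166405962	52.19		7.5
7	p15.3	20788779	20857393	14.57		6.0
7	p14.1	39890729	39952510	58.27		6.0
7	p14.1	40008069	40034702	45.06	CDC2L5	6.0
7	q31.2	116015401	116093417	15.38		11.9
7	q35	147108655	147152043	27.66	CNTNAP2	6.0
8	q12.1	59427474	59488208	41.16	UBXN2B	7.5
8	q12.1	59519371	59565778	15.08	CYP7A1	7.5
8	q24.3	145297206	145464363	45.47	BOP1	13.4
9	p23	11563590	11687635	54.01		6.0
9	q21.33	87357577	87392381	51.72	AGTPBP1	9.0
10	q25.1	109269991	109444702	43.5		6.0
10	q25.1	111391808	111534660	37.1		6.0
10	q25.3	116921563	116965495	106.98	ATRNL1	10.4
10	q25.3	117395507	117462466	37.34	ATRNL1	9.0
11	p13	36266146	36292214	57.54		6.0
11	q23.3	117486844	117510539	84.41	SCN4B	14.9
12	p13.2	11222379	11312714	55.35	PRB3	6.0
12	p12.3	15020696	15041656	57.25		7.5
12	p11.21	30798016	30861280	41.1		9.0
12	q12	34236852	36858944	7.09		6.0
12	q13.2	53311891	53382664	35.32		16.4
12	q13.2	54253884	54290994	40.42		13.4
12	q14.1	56621139	56633663	7.98	XRCC6BP1	9.0
12	q21.33	90946754	91022602	21.09		7.5
13	q14.11	43044213	43114392	45.6	ENOX1	11.9
13	q14.11	43114451	43143651	10.27	ENOX1	11.9
14	q22.1	48984150	49093570	25.59		6.0
14	q31.3	88397409	88411102	51.12	TTC8	9.0
14	q32.33	105080399	105354886	21.86	IgH	19.4
14	q32.33	105469384	105481523	57.67	IgH	11.9
14	q32.33	105787449	105834932	86.35	IgH	9.0
14	q32.33	105947052	105977946	61.5	IgH	16.4
15	q22.2	59803190	59933103	24.63	VPS13C	6.0
15	q24.3	74558533	74601045	56.45	SCAPER	9.0
16	q11.2	34083801	45122058	2.98	FLJ43980	6.0
17	q12	35221880	35241893	9.99	IKZF3	11.9
17	q12	35282145	35316098	55.96	GSDMB	16.4
17	q21.2	36666037	36724675	28.99	KRTAP17-1	6.0
17	q21.31	38255982	38261676	17.56	AOC3	7.5
17	q25.1	71511380	71527979	0.0	EVPL	6.0
19	q13.12	40328372	40338038	0.0	FXYD5	7.5
19	q13.42	61045704	61062298	66.29	NLRP4	20.9
20	p13	3365914	3411271	59.53	ATRN	9.0
20	p13	3553255	3588125	43.02	GFRA4	9.0
20	q12	40298330	40332059	0.0	PTPRT	22.4
20	q13.12	43765836	43768958	0.0	WFDC13	6.0
20	q13.32	57813291	57856200	9.32		9.0
20	q13.33	58011342	58074892	33.04	C20orf197	7.5
21	q22.11	31050355	31088151	10.58		6.0
22	q11.22	21520273	21588229	38.26	IgL	6.0
22	q12.3	34602119	34638273	0.0	RBM9	6.0
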