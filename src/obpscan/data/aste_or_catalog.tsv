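name	protein_accession	gene_id	chromosome	mw_reported_kda	pi_reported
AsteOR1	XP_035892088.1	LOC118502993	1	47.484	9.49
AsteOR2	XP_035917717.1	LOC118514681	1	47.46	9.51
AsteOR3	XP_035900263.1	LOC118506771	1	11.761	9.51
AsteOR4	XP_035918152.1	LOC118516006	1	29.498	8.69
AsteOR5	XP_035893454.1	LOC118503850	2	50.216	9.17
AsteOR6	XP_035893486.1	LOC118503863	2	30.798	7
AsteOR7	XP_035901553.1	LOC118507296	2	45.165	8.73
AsteOR8	XP_035899159.1	LOC118506317	2	97.083	9.08
AsteOR9	XP_035898901.1	LOC118506200	2	49.355	8.23
AsteOR10	XP_035898518.1	LOC118506022	2	45.771	8.7
AsteOR11	XP_035901800.1	LOC118507433	2	46.713	6.22
AsteOR12	XP_035903051.1	LOC118507903	2	46.521	6.55
AsteOR13	XP_035891168.1	LOC118502720	2	46.096	5.9
AsteOR14	XP_035899865.1	LOC118506605	2	52.647	8.83
AsteOR15	XP_035893072.1	LOC118503656	2	39.869	9.08
AsteOR16	XP_035893066.1	LOC118503653	2	47.581	9.26
AsteOR17	XP_035895309.1	LOC118504650	2	14.085	6.7
AsteOR18	XP_035890596.1	LOC118502471	2	43.074	7.17
AsteOR19	XP_035890597.1	LOC118502472	2	48.388	8.52
AsteOR20	XP_035897380.1	LOC118505546	2	43.686	7.6
AsteOR21	XP_035890600.1	LOC118502475	2	51.037	9.41
AsteOR22	XP_035903785.1	LOC118508262	2	53.873	8.11
AsteOR23	XP_035903780.1	LOC118508261	2	55.875	8.31
AsteOR24	XP_035890608.1	LOC118502484	2	46.469	8.91
AsteOR25	XP_035896260.1	LOC118505078	2	46.133	7.55
AsteOR26	XP_035914390.1	LOC118513096	3	46.464	9.36
AsteOR27	XP_035913964.1	LOC118512920	3	48.938	6.37
AsteOR28	XP_035910189.1	LOC118511343	3	53.323	6.59
AsteOR29	XP_035904929.1	LOC118509018	3	42.07	8.72
AsteOR30	XP_035904961.1	LOC118509031	3	43.592	9.29
AsteOR31	XP_035904965.1	LOC118509034	3	43.903	5.75
AsteOR32	XP_035907269.1	LOC118509993	3	44.707	8.63
AsteOR33	XP_035907274.1	LOC118509997	3	17.289	4.97
AsteOR34	XP_035907276.1	LOC118509999	3	43.583	5.65
AsteOR35	XP_035904780.1	LOC118508959	3	10.478	8.73
AsteOR36	XP_035907277.1	LOC118510000	3	32.545	6.1
AsteOR37	XP_035910820.1	LOC118511624	3	48.887	8.47
AsteOR38	XP_035908757.1	LOC118510691	3	43.658	8.99
AsteOR39	XP_035908756.1	LOC118510690	3	43.438	8.56
AsteOR40	XP_035908759.1	LOC118510692	3	43.242	9.03
AsteOR41	XP_035908990.1	LOC118510790	3	15.858	5.27
AsteOR42	XP_035907332.1	LOC118510050	3	32.201	8.45
AsteOR43	XP_035907338.1	LOC118510056	3	45.4	9.52
AsteOR44	XP_035916306.1	LOC118513983	3	33.276	5.81
AsteOR45	XP_035919246.1	LOC118517353	Unknown	31.278	6.55
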