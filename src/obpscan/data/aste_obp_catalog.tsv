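name	protein_accession	gene_id	class	chromosome	mw_reported_da	pi_reported
AsteOBP1	XP_035917841.1	LOC118504557	classic	X	18669	4.7
AsteOBP2	XP_035891203.1	LOC118504570	classic	X	16593	6.5
AsteOBP3	XP_035891204.1	LOC118510310	classic	X	16564	5.6
AsteOBP4	XP_035891207.1	LOC118510318	classic	X	16813	5.6
AsteOBP5	XP_035891740.1	LOC118510325	classic	X	15898	4.2
AsteOBP6	XP_035891741.1	LOC118510331	classic	X	14940	6.2
AsteOBP7	XP_035892015.1	LOC118502745	classic	2	15105	8.4
AsteOBP8	XP_035892546.1	LOC118502746	atypical	2	50208	8.2
AsteOBP9	XP_035892547.1	LOC118502748	atypical	2	39006	5.1
AsteOBP10	XP_035893080.1	LOC118503023	classic	2	17788	4.9
AsteOBP11	XP_035894183.1	LOC118503024	plus_c	2	22832	4.7
AsteOBP12	XP_035894335.1	LOC118503161	classic	2	15761	4.3
AsteOBP13	XP_035894381.1	LOC118503418	classic	2	16437	6.5
AsteOBP14	XP_035895118.1	LOC118503419	atypical	2	31279	8.4
AsteOBP15	XP_035895684.1	LOC118503662	classic	2	15844	6.3
AsteOBP16	XP_035895818.1	LOC118504157	classic	2	17738	8.9
AsteOBP17	XP_035895821.1	LOC118504227	classic	2	15028	4.8
AsteOBP18	XP_035897326.1	LOC118504259	atypical	2	24233	6.6
AsteOBP19	XP_035897725.1	LOC118504578	classic	2	16412	5.2
AsteOBP20	XP_035898485.1	LOC118504803	classic	2	16227	8.1
AsteOBP21	XP_035898834.1	LOC118504874	classic	2	19676	8.9
AsteOBP22	XP_035898836.1	LOC118504876	classic	2	16709	8.7
AsteOBP23	XP_035899548.1	LOC118505522	classic	2	17444	5.8
AsteOBP24	XP_035900970.1	LOC118505693	classic	2	13982	8.4
AsteOBP25	XP_035902367.1	LOC118506007	classic	2	16094	4.8
AsteOBP26	XP_035903187.1	LOC118506171	classic	2	14920	4.7
AsteOBP27	XP_035903789.1	LOC118506172	classic	2	18610	4.6
AsteOBP28	XP_035905778.1	LOC118506477	classic	2	17744	9.3
AsteOBP29	XP_035907589.1	LOC118507089	plus_c	2	21790	8.5
AsteOBP30	XP_035907591.1	LOC118507680	plus_c	2	21161	5.9
AsteOBP31	XP_035907600.1	LOC118507965	plus_c	2	22467	8.8
AsteOBP32	XP_035908250.1	LOC118508265	plus_c	2	23618	7.5
AsteOBP33	XP_035908252.1	LOC118509362	plus_c	3	19688	4.9
AsteOBP34	XP_035908253.1	LOC118510176	plus_c	3	19627	4.9
AsteOBP35	XP_035909003.1	LOC118510178	atypical	3	36926	6
AsteOBP36	XP_035910841.1	LOC118510185	classic	3	17618	8.4
AsteOBP37	XP_035914753.1	LOC118510478	atypical	3	31775	5.3
AsteOBP38	XP_035917598.1	LOC118510479	classic	3	15299	4.8
AsteOBP39	XP_035895071.1	LOC118510480	classic	3	20736	5.2
AsteOBP40	XP_035895083.1	LOC118510798	classic	3	15612	5.3
AsteOBP41	XP_035907843.1	LOC118511635	atypical	3	35623	5.8
AsteOBP42	XP_035907857.1	LOC118513288	atypical	3	33435	5.2
AsteOBP43	XP_035907868.1	LOC118514663	atypical	3	33188	5.2
AsteOBP44	XP_035907882.1	LOC118515263	atypical	Unknown	31914	5.4
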