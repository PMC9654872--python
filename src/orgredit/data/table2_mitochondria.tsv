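gene	genome_position	edited_nucleotide	amino_acid_change	editing_type	position_in_codon
atp9	54812	C20	S7→L7	C→T	2
atp9	54874	C82	L28→F28	C→T	1
atp9	54884	C92	S31→L31	C→T	2
nad6	85722	C446	S152→F152	C→T	2
cox2	138085	C742	R248→W248	C→T	1
cox2	138129	C698	T233→M233	C→T	2
cox2	138195	C632	S211→L211	C→T	2
cox2	138246	C581	S194→L194	C→T	2
cox2	138270	C557	P186→L186	C→T	2
cox2	138283	C544	P182→S182	C→T	1
cox2	138351	C476	S159→L159	C→T	2
cox2	138366	C461	P154→L154	C→T	2
cox2	138384	C443	T148→M148	C→T	2
cox2	138448	C379	R127→W127	C→T	1
cox2	138549	C278	P93→L93	C→T	2
cox2	138574	C253	R85→W85	C→T	1
cox2	138664	C163	R55→W55	C→T	1
cox2	138666	C161	S54→L54	C→T	2
cox2	138756	C71	S24→F24	C→T	2
rps12	196313	C284	S95→F95	C→T	2
rps12	196401	C196	H66→Y66	C→T	1
rps12	196497	C100	R34→C34	C→T	1
rps12	196526	C71	S24→L24	C→T	2
nad3	196959	C43	P15→S15	C→T	1
rps1	239984	C107	S36→F36	C→T	2
rps1	240035	C56	P19→L19	C→T	2
matR	272897	C1775	P592→L592	C→T	2
matR	272950	C1722	Y574→Y574	C→T	3
matR	272984	C1688	P563→L563	C→T	2
matR	273005	C1667	S556→F556	C→T	2
ccmFn	297223	C1423	R475→W475	C→T	1
ccmFn	297286	C1486	L496→F496	C→T	1
ccmFn	297355	C1555	P519→S519	C→T	1
atp4	323099	C416	T139→I139	C→T	2
atp4	323109	C406	P136→S136	C→T	1
atp4	323120	C395	S132→L132	C→T	2
atp4	323264	C251	P84→L84	C→T	2
atp4	323267	C248	P83→L83	C→T	2
atp4	323288	C227	P76→L76	C→T	2
atp4	323300	C215	S72→L72	C→T	2
atp4	323397	C118	R40→C40	C→T	1
atp4	323426	C89	S30→L30	C→T	2
atp4	323444	C71	S24→L24	C→T	2
atp4	323456	C59	S20→F20	C→T	2
nad41	323824	C149	S50→L50	C→T	2
nad41	323872	C101	S34→L34	C→T	2
atp1	396108	C1039	P347→S347	C→T	1
atp1	396133	C1064	S355→L355	C→T	2
atp1	396247	C1178	S393→L393	C→T	2
atp1	396285	C1216	L406→F406	C→T	1
atp1	396361	C1292	P431→L431	C→T	2
atp1	396484	C1415	P472→L472	C→T	2
rps7	421118	C332	S111→L111	C→T	2
rpl10	431602	C83	S28→L28	C→T	2
rpl10	431620	C101	S34→L34	C→T	2
rpl10	431758	C239	S80→L80	C→T	2
rpl10	431833	C314	S105→L105	C→T	2
ccmB	432360	C554	S185→L185	C→T	2
ccmB	432363	C551	S184→L184	C→T	2
ccmB	432400	C514	R172→C172	C→T	1
ccmB	432402	C512	S171→F171	C→T	2
ccmB	432411	C503	P168→L168	C→T	2
ccmB	432420	C494	S165→L165	C→T	2
ccmB	432429	C485	S162→L162	C→T	2
ccmB	432438	C476	P159→L159	C→T	2
ccmB	432439	C475	P159→L159	C→T	1
ccmB	432477	C467	S156→L156	C→T	2
ccmB	432486	C428	S143→L143	C→T	2
ccmB	432490	C424	R142→C142	C→T	1
ccmB	432535	C379	L127→L127	C→T	1
ccmB	432547	C367	R123→W123	C→T	1
ccmB	432576	C338	P113→L113	C→T	2
ccmB	432601	C313	R105→W105	C→T	1
ccmB	432610	C304	R102→C102	C→T	1
ccmB	432628	C286	R96→W96	C→T	1
ccmB	432720	C194	P65→F65	C→T	2
ccmB	432721	C193	P65→F65	C→T	1
ccmB	432735	C179	P60→L60	C→T	2
ccmB	432742	C172	P58→S58	C→T	1
ccmB	432750	C164	P55→L55	C→T	2
ccmB	432754	C160	P54→S54	C→T	1
ccmB	432760	C154	R52→W52	C→T	1
ccmB	432765	C149	P50→L50	C→T	2
ccmB	432766	C148	P50→L50	C→T	1
ccmB	432777	C137	S46→F46	C→T	2
ccmB	432786	C128	S43→L43	C→T	2
ccmB	432827	C87	I29→I29	C→T	3
ccmB	432834	C80	S27→L27	C→T	2
ccmB	432843	C71	P24→L24	C→T	2
ccmB	432871	C43	P15→S15	C→T	1
ccmB	432886	C28	S10→L10	C→T	1
atp6	450313	C548	S183→F183	C→T	2
atp6	450607	C254	S85→L85	C→T	2
atp6	450824	C37	P12→S12	C→T	1
nad5	504064	C155	P52→L52	C→T	2
nad5	505005	C245	P82→L82	C→T	2
nad5	505035	C275	S92→F92	C→T	2
nad5	505121	C361	P121→F121	C→T	1
nad5	505122	C362	P121→F121	C→T	2
nad5	505137	C377	P126→L126	C→T	2
nad5	505161	C401	S134→F134	C→T	2
nad5	505269	C509	P170→L170	C→T	2
nad5	505302	C542	P181→L181	C→T	2
nad5	505311	C551	S184→L184	C→T	2
nad5	505371	C611	A204→V204	C→T	2
nad5	505392	C632	S211→F211	C→T	2
nad5	505394	C634	R212→C212	C→T	1
nad5	505439	C679	L227→F227	C→T	1
nad5	505476	C716	S239→L239	C→T	2
nad5	505488	C728	S243→L243	C→T	2
nad5	505598	C838	P280→S280	C→T	1
orf115b	506667	C77	S50→L50	C→T	2
ccmFc	553661	C1133	P378→L378	C→T	2
ccmFc	553682	C1154	S385→L385	C→T	2
ccmFc	553790	C1262	S421→L421	C→T	2
sdh3	576179	C67	P23→S23	C→T	1
sdh3	576186	C74	S25→F25	C→T	2
rpl5	646335	C92	S31→L31	C→T	2
rpl5	646412	C169	P57→S57	C→T	1
rpl5	646415	C172	R58→C58	C→T	1
rpl5	646693	C450	I150→I150	C→T	3
rpl5	646761	C518	P173→L173	C→T	2
rpl5	646764	C521	P174→L174	C→T	2
rps14	647079	C271	P91→S91	C→T	1
cob	648551	C118	P40→S40	C→T	1
cob	648611	C178	H60→Y60	C→T	1
cob	648719	C286	L96→F96	C→T	1
cob	648731	C298	H100→Y100	C→T	1
cob	648758	C325	H109→Y109	C→T	1
cob	648791	C358	R120→W120	C→T	1
cob	648852	C419	P140→L140	C→T	2
cob	649001	C568	H150→Y150	C→T	1
cob	649113	C680	S227→F227	C→T	2
cob	649241	C808	P270→S270	C→T	1
cob	649286	C853	H285→Y285	C→T	1
cob	649341	C908	P303→L303	C→T	2
cob	649347	C914	S305→F305	C→T	2
cob	649415	C982	H327→Y327	C→T	1
cob	649448	C1015	R339→C339	C→T	1
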