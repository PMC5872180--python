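gene	protein_id	origin	degree	betweenness	node_class	GSE8401_direction	GSE8401_p_adj	GSE46517_direction	GSE46517_p_adj	GSE15605_direction	GSE15605_p_adj
AKT1	ENSP00000270202	ST	32	0.03034247	NH-B	NS	0.073094859	Down	0.002572769	NS	0.99159187
CALM1	ENSP00000349467	CON	46	0.04297522	HB	NS	0.420640218	Up	0.014354422	NS	0.102753445
CTNNB1	ENSP00000344456	ST	49	0.09934346	HB	Up	0.000112883	Up	5.22113e-05	NS	0.134736908
EGFR	ENSP00000275493	Ca	41	0.02867496	HB	NS	0.454469806	Down	4.09354e-18	NS	0.372953188
ESR1	ENSP00000206249	CON	37	0.03902762	NH-B	NS	0.34361801	NS	0.691913409	NS	0.858356832
GABRR1	ENSP00000412673	CON	4	0.02033756	NH-B	NS	0.516750581	NS	0.178807962	Up	0.030236148
GNAQ	ENSP00000286548	Ca	69	0.08508797	HB	Up	0.014769785	Up	0.038122837	NS	0.174777485
GSK3B	ENSP00000324806	ST	31	0.03985954	NH-B	Down	4.43231e-06	Down	2.75596e-10	NS	0.542667881
GSTP1	ENSP00000381607	CON	4	0.02033756	NH-B	Down	3.14081e-05	Down	2.61693e-06	NS	0.274434846
HDAC1	ENSP00000362649	CON	27	0.03262084	NH-B	NS	0.213434449	NS	0.710999269	NS	0.865172009
IGF1	ENSP00000302665	CON	28	0.04312205	NH-B	NS	0.697266013	NS	0.431465367	NS	0.66956775
ITPR3	ENSP00000363435	Ca	22	0.01942364	NH-B	NS	0.269623007	NS	0.671875922	NS	0.742562621
JUN	ENSP00000360266	CON	31	0.03792962	NH-B	Down	8.92807e-06	NS	0.171366276	NS	0.900656682
MAPK1	ENSP00000215832	ST	42	0.05561423	HB	Up	0.000412172	NS	0.429091242	NS	0.608460569
MAPK14	ENSP00000229794	ST	34	0.02912488	NH-B	NS	0.605738821	Up	0.038642425	NS	0.358766287
MAPK3	ENSP00000263025	ST	33	0.02244545	NH-B	Down	1.10052e-05	Down	0.01074679	NS	0.999319565
MYC	ENSP00000367207	ST	34	0.03598441	NH-B	NS	0.602836201	NS	0.274057104	NS	0.449615647
NCOR1	ENSP00000268712	CON	21	0.02875081	NH-B	NS	0.627351808	NS	0.257849878	NS	0.148831132
PIK3R1	ENSP00000274335	ST	69	0.05441236	HB	NS	0.383906559	Down	0.030059149	NS	0.057825554
PPP1CC	ENSP00000335084	CON	22	0.01965509	NH-B	Up	1.52233e-05	Up	3.22551e-05	NS	0.307997432
PRKACA	ENSP00000309591	CON	51	0.0837037	HB	Down	0.00193898	Down	0.006166758	NS	0.056947292
PRKCA	ENSP00000408695	Ca	55	0.03906664	HB	Up	0.003860994	NS	0.227826787	NS	0.934220679
PTPN11	ENSP00000340944	ST	34	0.02374219	NH-B	Up	0.039908343	Up	0.009092992	Up	0.048264037
SMAD2	ENSP00000262160	ST	29	0.02336588	NH-B	Up	0.009466433	NS	0.924719732	NS	0.23296179
SMAD3	ENSP00000332973	ST	28	0.02392531	NH-B	NS	0.975647588	NS	0.09794078	NS	0.219862918
SMAD4	ENSP00000341551	ST	35	0.03753624	NH-B	Up	5.56315e-06	Up	0.000292094	NS	0.141417242
TCF3	ENSP00000262965	ST	18	0.02573384	NH-B	NS	0.803481248	NS	0.217139092	NS	0.260191349
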