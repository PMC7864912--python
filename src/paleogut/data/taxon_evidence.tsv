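species	reads	reads_pmds1	doc	breadth_pct	ct5_pct	neg_delta
Alistipes finegoldi	340	80	0.003	0.3	11.3	1
Alistipes shahii	338	68	0.003	0.3	11.9	1
Alistipes indistinctus	245	62	0.003	0.2	11.4	1
Alistipes timonensis	303	55	0.003	0.3	11.1	1
Alistipes senegalensis	376	73	0.003	0.3	13.4	1
Alistipes ihumii	406	93	0.005	0.4	10.9	1
Anaeromassilibacillus senegalensis	233	54	0.002	0.2	10.2	1
Bifidobacterium callitrichos	322	65	0.003	0.3	10.9	1
Bifidobacterium subtile	288	54	0.003	0.3	11.7	1
Bittarella massiliensis	474	110	0.006	0.5	10.5	1
Catonella morbi	543	80	0.008	0.8	10.5	1
Clostridium perfringes	1392	194	0.03	0.7	12.6	1
Collinsella ihuae	513	106	0.006	0.5	10.2	1
Collinsella phocaeensis	386	83	0.003	0.3	11.6	1
Desulfovibrio alaskensis	286	51	0.002	0.2	10.2	1
Desulfovibrio alkalitolerans	652	124	0.007	0.6	10.3	1
Desulfovibrio dechloracetivorans	608	122	0.005	0.4	10.6	1
Desulfovibrio fairfieldensis	383	74	0.003	0.3	12.1	1
Desulfovibrio gracilis	289	56	0.003	0.3	11.1	1
Desulfovibrio legallii	374	78	0.004	0.4	10.2	1
Desulfovibrio oxyclinae	356	84	0.003	0.3	10.3	1
Desulfovibrio vulgaris	668	133	0.005	0.5	10.5	1
Faecalibacterium prausnitzii	287	61	0.003	0.3	12.7	1
Fournierella massiliensis	313	68	0.003	0.2	11.1	1
Hungatella (Clostridium) hatheway	276	53	0.001	0.1	10.4	1
Klebsiella pneumoniae	390	82	0.002	0.2	10.9	1
Paeniclostridium sordelli	780	86	0.01	0.5	10.5	1
Papillibacter cinnamivorans	284	53	0.003	0.3	11.3	1
Prevotella timonensis	220	96	0.004	0.1	15.9	1
Prevotella saccharolytica	494	61	0.008	0.8	12.1	1
Pseudoescherichia vulneris	278	56	0.002	0.2	12.2	1
Pseudosulfovibrio indicus	605	123	0.005	0.5	10.3	1
Rikenella microfusus	276	54	0.003	0.3	12.0	1
Ruthenibacterium lactatiformans	315	57	0.002	0.2	10.1	1
Siccibacter turicensis	311	58	0.002	0.2	11.2	1
Yokenella regensburgei	258	56	0.002	0.1	11.8	1
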