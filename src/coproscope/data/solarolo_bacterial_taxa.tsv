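taxon	reads	pmds_gt1_reads	depth	breadth_pct	ct5_pct	neg_delta
Bifidobacterium adolescentis	790	177	0.02	1.9	10.1	1
Bifidobacterium angulatum	4851	387	0.1	14	10.1	1
Bifidobacterium breve	2547	188	0.1	6.6	9.2	1
Bifidobacterium pseudocatenulatum	3246	803	0.1	7.9	8.8	1
Blautia hansenii	2949	573	0.1	6.4	9.5	1
Blautia obeum	1031	171	0.02	1.8	9	1
Blautia wexlerae	1429	224	0.02	2.2	8.5	1
Catenibacterium mitsuokai	3125	453	0.08	8	11.3	1
Clostridium baratii	7043	391	0.2	2.8	10	1
Clostridium bornimense	1504	320	0.03	3.2	8.1	1
Clostridium butyricum	1216	170	0.02	1.9	9.5	1
Clostridium celatum	2126	236	0.04	4	11.7	1
Clostridium disporicum	915	173	0.02	1.2	13	1
Clostridium niameyense	511	97	0.01	1.5	12.6	1
Clostridium novyi	1547	382	0.04	4.22	10.6	1
Clostridium perfringens	5264	680	0.1	12	9.5	1
Clostridium septicum	3007	110	0.07	6.6	13.6	1
Clostridium thermobutyricum	5242	210	0.1	12	8.3	1
Clostridium thiosulfatireducens	778	194	0.007	0.6	9.2	1
Clostridium ventriculi	4775	295	0.15	15	10.2	0.99
Collinsella aerofaciens	4074	781	0.1	11	9.5	1
Collinsella bouchesdurhonensis	2579	351	0.08	7.8	8.7	1
Collinsella intestinalis	3652	589	0.1	12	9	1
Collinsella stercoris	700	130	0.01	1.4	8.7	1
Coprococcus comes	2935	294	0.06	6	10.2	1
Dorea formicigenerans	3342	291	0.07	6.5	10.8	1
Enterococcus casseliflavus	590	54	0.009	0.9	9.7	1
Enterococcus faecalis	2269	137	0.05	5.3	9.7	1
Enterococcus faecium	1624	61	0.04	4	7.8	1
Escherichia coli	1417	155	0.01	1.4	11.2	1
Faecalibacterium prausnitzii	613	98	0.01	1.2	8.1	1
Holdemanella biformis	3329	696	0.08	8.2	11.2	1
Intestinibacter bartlettii	4026	331	0.1	9.6	9.5	1
Lactobacillus acidophilus	643	50	0.02	1.7	11.7	1
Lactobacillus brevis	5353	453	0.1	13	10	1
Lactobacillus buchneri	765	116	0.02	1.9	10.2	1
Lactobacillus diolivorans	872	62	0.02	1.7	10.8	1
Lactobacillus manihotivorans	672	165	0.01	1.1	12.1	1
Lactobacillus mucosae	2901	739	0.08	7.7	8.9	1
Lactobacillus murinus	923	87	0.03	2.7	12	1
Lactobacillus parabuchneri	8659	1298	0.2	0.2	9.4	1
Lactobacillus paracasei	2239	151	0.05	4.6	9.4	1
Lactobacillus paraplantarum	1444	316	0.03	2.6	9.7	1
Lactobacillus reuteri	3268	645	0.1	11	8.6	1
Lactobacillus ruminis	4463	388	0.1	14	9.3	1
Lactobacillus salivarius	973	125	0.04	3.5	9.3	1
Lactobacillus vaccinostercus	1878	198	0.05	4.9	8.9	1
Lactococcus petauri	4407	363	0.1	13	9.6	1
Methanobrevibacter millerae	2994	393	0.08	7.7	10.4	1
Prevotella copri	1186	136	0.02	1.8	9.2	1
Romboutsia ilealis	946	218	0.02	2.5	11.1	1
Romboutsia timonensis	3756	291	0.09	8.9	10.5	1
Roseburia faecis	2055	218	0.04	3.8	9.2	1
Roseburia inulinivorans	932	132	0.02	1.7	9.8	1
Ruminococcus bromii	2979	261	0.09	8.6	9.4	1
Turicibacter sanguinis	3543	158	0.08	8.4	12.9	1
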