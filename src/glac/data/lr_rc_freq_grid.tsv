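child_class	0	0.0-0.1	0.1-0.2	0.2-0.3	0.3-0.4	0.4-0.5	0.5-0.6	0.6-0.7	0.7-0.8	0.8-0.9	0.9-0.99	1
0	70628	79484	89	0	0	0	0	0	0	0	0	0
0.0-0.1	6772	142746	16122	2433	248	15	0	0	0	0	0	0
0.1-0.2	69	17442	15396	7502	2080	393	32	0	0	0	0	0
0.2-0.3	0	3453	7799	8157	4679	1937	427	61	1	0	0	0
0.3-0.4	0	507	2343	5181	5020	3846	1330	376	22	0	0	0
0.4-0.5	0	45	486	1915	3621	3482	2421	1219	351	52	0	0
0.5-0.6	0	1	93	457	1517	2503	2904	2690	1268	288	9	0
0.6-0.7	0	0	1	69	361	1204	2824	3665	2696	1121	197	0
0.7-0.8	0	0	0	27	29	293	1378	2717	3859	2993	1045	0
0.8-0.9	0	0	0	0	0	19	260	1132	3115	5179	4163	15
0.9-0.99	0	0	0	0	0	0	6	148	908	4729	35883	1431
1	0	0	0	0	0	0	0	0	0	4	23967	22261
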