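child_class	0	0.0-0.1	0.1-0.2	0.2-0.3	0.3-0.4	0.4-0.5	0.5-0.6	0.6-0.7	0.7-0.8	0.8-0.9	0.9-0.99	1
0	603	20998	37678	13559	3303	1008	265	48	7	0	0	0
0.0-0.1	34735	84372	57296	34668	16139	9253	4400	1777	802	226	10	0
0.1-0.2	2383	20182	7516	4734	2734	2087	1344	760	431	152	6	0
0.2-0.3	322	10739	5225	3188	2120	1669	1189	697	418	154	20	0
0.3-0.4	90	5858	3895	2340	1621	1367	1074	678	409	181	42	0
0.4-0.5	9	3896	3291	1837	1305	1111	956	604	438	193	52	0
0.5-0.6	1	1815	2755	1760	1177	1216	1017	796	643	312	90	0
0.6-0.7	3	1191	2709	1861	1422	1375	1240	875	725	451	156	0
0.7-0.8	0	595	2596	1864	1366	1482	1277	1075	933	675	353	4
0.8-0.9	0	127	2098	2124	1446	1510	1434	1389	1459	1387	1288	104
0.9-0.99	0	14	1218	3070	2894	3730	5264	6714	10923	15319	13875	2243
1	0	0	1	8	21	120	505	1192	4451	11460	5912	37
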