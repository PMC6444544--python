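gene	chromosome	transcript_id	aa_length	mw_kda
TaHsfA1-1	4A	AA0958570	521	57.36
TaHsfA1-2	5B	AA1285550	529	58.19
TaHsfA1-3	5D	AA1410370	522	57.46
TaHsfA2-1	5A	AA1215960	346	38.99
TaHsfA2-2	5B	AA2081150	353	39.73
TaHsfA2-3	5D	AA1442920	348	38.91
TaHsfA2-4	2A	AA0357000	413	45.61
TaHsfA2-5	2B	AA0492290	405	44.93
TaHsfA2-6	2D	AA0573260	412	45.44
TaHsfA2-7	4A	AA1018260	341	39.61
TaHsfA2-8	4B	AA1062420	341	39.6
TaHsfA2-9	4D	AA1126990	341	39.5
TaHsfA2-10	5A	AA1256510	372	41.14
TaHsfA2-11	U		373	41.44
TaHsfA2-12	5D	AA1405180	377	41.6
TaHsfA2-13	1A	AA0048030	364	41.03
TaHsfA2-14	1B	AA0114190	364	41.03
TaHsfA2-15	1D	AA0199110	370	42.05
TaHsfA2-16	3A	AA0636800	397	44.24
TaHsfA2-17	3B	AA0745290	433	48.01
TaHsfA2-18	3D		407	46.23
TaHsfA3-1	2A	AA0373860	467	51.63
TaHsfA3-2	2A	AA0367680	502	55.45
TaHsfA3-3	2B	AA0455720	475	52.09
TaHsfA3-4	2D	AA0576700	499	54.79
TaHsfA4-1	1A	AA0026630	443	49.57
TaHsfA4-2	1B	AA0108940	445	49.88
TaHsfA4-3	1D	AA0193800	442	49.71
TaHsfA4-4	3A	AA0661360	432	48.38
TaHsfA4-5	3B	AA0790580	441	49.47
TaHsfA4-6	3D	AA0847210	433	48.46
TaHsfA5-1	6A	AA1567660	458	49.88
TaHsfA5-2	6B	AA1650270	455	49.93
TaHsfA5-3	6D	AA1745290	458	49.87
TaHsfA6-1	7A	AA1799040	310	33.78
TaHsfA6-2	7B	AA1908250	351	37.9
TaHsfA6-3	7D	AA2004680	351	37.98
TaHsfA9-1	4A	AA1009080	383	42.86
TaHsfA9-2	4B	AA1071190	384	42.88
TaHsfA9-3	4D	AA1142510	384	42.93
TaHsfB1-1	5A	AA1196580	298	32.15
TaHsfB1-2	5B	AA1307960	298	32.29
TaHsfB1-3	5D	AA1418380	298	32.06
TaHsfB2-1	2A	AA0301090	295	31.99
TaHsfB2-2	2D	AA2166870	209	22.73
TaHsfB2-3	7A	AA1829250	374	40.46
TaHsfB2-4	7B	AA1935670	374	40.34
TaHsfB2-5	7D	AA2015840	367	39.79
TaHsfB2-6	5A	AA0058470	404	42.04
TaHsfB2-7	5B	AA1315570	701	73.93
TaHsfB2-8	5D	AA1415650	397	41.11
TaHsfB4-1	2A	AA2122890	320	35.26
TaHsfB4-2	2D	AA0597540	320	35.32
TaHsfB4-3	5A	AA1189330	388	41.36
TaHsfB4-4	5B	AA1293070	388	41.46
TaHsfB4-5	5D	AA1418740	388	41.4
TaHsfC1-1	3A	AA0634640	294	32.58
TaHsfC1-2	3B	AA0722380	325	35.73
TaHsfC1-3	3D	AA0860000	321	35.39
TaHsfC1-4	3A	AA0670400	277	31.16
TaHsfC1-5	3B	AA0722680	304	33.89
TaHsfC1-6	3D	AA0849120	225	25.63
TaHsfC1-7	3A	AA0614700	236	26.06
TaHsfC1-8	3B	AA0780810	227	24.69
TaHsfC1-9	3D	AA0873000	241	26.41
TaHsfC2-1	5A	AA2086000	268	30.0
TaHsfC2-2	7A	AA1794130	266	28.23
TaHsfC2-3	7B	AA1874420	244	26.12
TaHsfC2-4	7D	AA2011440	265	28.18
TaHsfC3-1	4D	AA1147440	276	30.27
TaHsfC3-2	5A	AA1225450	274	30.36
TaHsfC3-3	4B	AA1034070	257	28.73
TaHsfC3-4	3B	AA0791830	274	29.98
TaHsfC3-5	3B	AA0777840	230	25.57
TaHsfC3-6	4B	AA1034080	257	28.5
TaHsfC3-7	4B	AA1067170	268	30.0
TaHsfC3-8	4B	AA1045990	273	29.46
TaHsfC3-9	U	AA1138930	276	29.86
TaHsfC3-10	5A	AA1241720	273	30.18
TaHsfC3-11	U	AA1138960	248	26.43
TaHsfC3-12	3B	AA0830650	237	26.13
TaHsfC3-13	4B	AA1040480	248	26.15
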