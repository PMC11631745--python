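variable	level	n_all	denom_all	pct_all	n_adeno	denom_adeno	pct_adeno	n_squam	denom_squam	pct_squam
histology	adenocarcinoma	5523	7606	73
histology	squamous	2083	7606	27
sex	female	3881	7603	51	3058	5521	55.4	823	2082	39.5
sex	male	3722	7603	49	2463	5521	44.6	1259	2082	60.5
age_group	<=40	44	7606	0.6	39	5523	0.7	5	2083	0.2
age_group	41-50	153	7606	2	136	5523	2.5	17	2083	0.8
age_group	51-60	832	7606	10.9	653	5523	11.8	179	2083	8.6
age_group	61-70	2589	7606	34	1854	5523	33.6	735	2083	35.3
age_group	71-80	2758	7606	36.3	1940	5523	35.1	818	2083	39.3
age_group	81-90	1145	7606	15.1	837	5523	15.2	308	2083	14.8
age_group	>90	85	7606	1.1	64	5523	1.2	21	2083	1
specimen_site	primary	5352	7606	70.4	3618	5523	65.5	1734	2083	83.2
specimen_site	advanced	1436	7606	18.9	1203	5523	21.8	233	2083	11.2
specimen_site	metastatic	818	7606	10.8	702	5523	12.7	116	2083	5.6
stage_known	unknown	4975	7606	65.4	3513	5523	63.6	1462	2083	70.2
stage_known	known	2631	7606	34.6	2010	5523	36.4	621	2083	29.8
stage	i	301	2631	11.4	246	2010	12.2	55	621	8.9
stage	ii	166	2631	6.3	109	2010	5.4	57	621	9.2
stage	iii	422	2631	16	262	2010	13	160	621	25.8
stage	iv	1742	2631	66.2	1393	2010	69.3	349	621	56.2
tier_positive	guideline_indicated	3328	7606	43.8	3176	5523	57.5	152	2083	7.3
tier_positive	trial_or_other_tumor	5887	7606	77.4	4385	5523	79.4	1502	2083	72.1
tier_positive	pathogenic_unknown	1641	7606	21.6	1064	5523	19.3	577	2083	27.7
tmb_level	very_high	841	6705	12.5	645	4865	13.3	196	1840	10.7
tmb_level	high	2027	6705	30.2	1258	4865	25.9	769	1840	41.8
tmb_level	not_high	3837	6705	57.2	2962	4865	60.9	875	1840	47.6
pdl1_level	high	1897	7558	25.1	1416	5487	25.8	481	2071	23.2
pdl1_level	low	2848	7558	37.7	1927	5487	35.1	921	2071	44.5
pdl1_level	negative	2813	7558	37.2	2144	5487	39.1	669	2071	32.3
msi	high	23	6708	0.3	9	4863	0.2	14	1845	0.8
msi	stable	6685	6708	99.7	4854	4863	99.8	1831	1845	99.2
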