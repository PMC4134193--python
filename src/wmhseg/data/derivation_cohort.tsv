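patient	side	group	semi_auto_ml	auto_ml	delta_vol_pct	demar	si_pct	sen_pct	spe_pct
1	R	wmh_only	7.954	7.994	0.5	0.65	96.759	97.005	99.996
2	L	wmh_only	15.019	14.447	-3.8	0.64	95.266	93.454	99.994
2	R	wmh_only	11.459	12.490	9.0	0.66	94.843	99.112	99.984
3	L	wmh_only	22.525	17.862	-20.7	0.62	87.954	78.849	99.998
4	L	wmh_only	15.159	9.018	-40.5	0.59	73.798	58.850	99.999
4	R	wmh_infarct	13.072	8.747	-33.1	0.60	80.089	66.840	100.000
5	L	wmh_only	3.945	4.405	11.7	0.66	91.489	96.827	99.990
5	R	wmh_infarct	5.766	5.495	-4.7	0.66	79.168	77.311	99.983
6	L	wmh_infarct	11.335	18.739	65.3	0.73	59.643	79.124	99.853
6	R	wmh_only	10.338	18.624	80.2	0.75	61.475	86.112	99.854
7	L	wmh_infarct	12.495	14.728	17.9	0.56	51.877	56.512	99.899
7	R	wmh_only	20.637	14.965	-27.5	0.58	83.989	72.448	100.000
8	L	wmh_only	9.009	4.746	-47.3	0.57	68.428	52.238	99.999
8	R	wmh_infarct	6.452	3.208	-50.3	0.56	66.422	49.725	100.000
9	L	wmh_only	18.012	12.016	-33.3	0.60	79.194	66.012	99.998
9	R	wmh_only	11.779	11.008	-6.5	0.65	92.412	89.391	99.993
10	L	wmh_only	2.362	4.427	87.4	0.74	64.883	93.246	99.967
10	R	wmh_infarct	4.839	8.167	68.8	0.74	55.128	74.084	99.931
11	L	wmh_only	4.041	1.533	-62.1	0.55	55.008	37.939	100.000
11	R	wmh_infarct	3.297	1.143	-65.3	0.58	51.497	34.677	100.000
12	L	wmh_only	10.573	9.938	-6.0	0.65	92.420	89.647	99.993
12	R	wmh_infarct	4.625	6.901	49.2	0.68	61.933	77.173	99.952
13	L	wmh_infarct	4.841	6.344	31.0	0.67	84.677	97.821	99.980
13	R	wmh_infarct	1.767	3.391	91.9	0.73	62.781	91.642	99.978
14	L	wmh_only	1.692	2.148	27.0	0.68	77.813	88.305	99.989
14	R	wmh_only	0.412	0.339	-17.6	0.65	79.570	72.549	99.999
15	L	wmh_only	1.892	1.897	0.2	0.65	94.503	94.614	99.998
15	R	wmh_only	2.548	3.944	54.8	0.70	77.816	99.130	99.979
16	L	wmh_infarct	21.281	19.794	-7.0	0.64	96.309	92.945	100.000
16	R	wmh_only	16.142	16.341	1.2	0.66	94.468	95.050	99.987
17	L	wmh_only	27.383	24.070	-12.1	0.63	93.486	87.832	100.000
17	R	wmh_infarct	11.125	20.656	85.7	0.65	64.066	91.511	99.856
18	L	wmh_only	2.233	3.057	36.9	0.68	80.737	95.635	99.986
18	R	wmh_infarct	2.273	2.074	-8.8	0.66	81.142	77.583	99.995
19	L	wmh_only	3.259	2.499	-23.3	0.61	86.796	76.672	100.000
19	R	wmh_only	2.184	2.567	17.5	0.68	86.646	94.235	99.993
20	L	wmh_only	0.736	0.683	-7.2	0.65	94.198	90.789	100.000
20	R	wmh_only	0.465	0.756	62.5	0.70	74.603	97.917	99.996
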