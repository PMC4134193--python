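patient	side	group	semi_auto_ml	auto_ml	delta_vol_pct	si_pct	sen_pct	spe_pct
1	L	wmh_only	12.421	12.500	0.6	92.212	92.508	99.985
1	R	wmh_only	11.605	13.954	20.2	87.621	96.487	99.959
2	L	wmh_only	3.408	4.373	28.3	84.484	96.445	99.983
2	R	wmh_infarct	3.210	5.624	75.2	71.207	97.987	99.961
3	L	wmh_infarct	0.864	0.758	-12.3	79.235	74.359	99.998
3	R	wmh_only	0.944	1.143	21.1	86.624	95.775	99.997
4	L	wmh_infarct	4.059	2.736	-32.6	80.542	67.422	100.000
4	R	wmh_only	5.531	4.741	-14.3	89.863	83.450	99.998
5	L	wmh_only	1.809	1.814	0.3	88.501	88.630	99.997
5	R	wmh_only	1.376	1.329	-3.4	92.008	90.421	99.999
6	L	wmh_only	1.681	1.065	-36.6	77.601	63.401	100.000
6	R	wmh_infarct	1.095	1.259	15.0	80.247	86.283	99.996
7	L	wmh_only	1.413	1.825	29.2	85.287	97.714	99.993
7	R	wmh_infarct	0.812	0.864	6.4	71.807	74.129	99.996
8	L	wmh_only	1.208	0.823	-31.9	81.039	68.122	100.000
8	R	wmh_only	1.065	0.791	-25.7	80.682	70.297	99.999
9	L	wmh_infarct	0.664	0.630	-5.2	89.888	87.591	99.999
9	R	wmh_only	0.223	0.184	-17.5	59.524	54.348	99.999
10	L	wmh_only	1.001	0.630	-37.1	76.238	62.097	100.000
10	R	wmh_infarct	0.929	0.420	-54.8	62.275	45.217	100.000
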