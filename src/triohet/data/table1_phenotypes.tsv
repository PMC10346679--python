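environment	timepoint	trait	units	p1_mean	p1_sd	p2_mean	p2_sd	f1_mean	f1_sd	mph_printed	mph_flag	hph_printed	hph_flag	note
early	1D	leaf_length	cm	28.17	1.485	25.2	1.92	30.4	2.32	13.9	*	7.9
early	1D	leaf_width	cm	2.02	0.107	2.18	0.33	2.38	0.30	13.3	*	9.1	*
early	1D	leaf_area	cm2	42.68		41.2		54.26		29.3	**	27.1	**
early	1D	spikelet_weight	g	6.7		5.68		7.3		17.9	**	8.9
early	10D	leaf_length	cm	31.8	3.585	30.15	1.80	30.18	1.29	-2.6		-5
early	10D	leaf_width	cm	2.07	0.080	2.33	0.22	2.35	0.28	6.8		0.8
early	10D	leaf_area	cm2	49.37		52.69		53.19		4.2		0.1		hph_print_mismatch
early	10D	tgw	g	24.86		14.77		20.42		2.81		-17.8	**	mph_suspect_typo
middle	1D	leaf_length	cm	27		38.5		44.1		34.7	**	14.5
middle	1D	leaf_width	cm	1.93		2		2.1		6.9		5
middle	1D	leaf_area	cm2	39.08		57.75		69.46		43.4	**	20.2	**
middle	1D	spikelet_weight	g	5.03		4.25		4.84		4.3		-3.7
middle	10D	leaf_length	cm	31.37		40.78		43.68		21.1	**	7.1
middle	10D	leaf_width	cm	2.11		2.22		2.28		5.3		2.7
middle	10D	leaf_area	cm2	49.64		67.9		74.69		27.1	**	10
middle	10D	tgw	g	29.06		14.64		21.1		-3.4		-27.3	**
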