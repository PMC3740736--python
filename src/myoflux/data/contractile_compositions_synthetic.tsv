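protein_id	alanine	arginine	asparagine	aspartate	cysteine	glutamate	glutamine	glycine	histidine	isoleucine	leucine	lysine	methionine	phenylalanine	proline	serine	threonine	tryptophan	tyrosine	valine
actin	37	20	18	24	2	36	16	20	9	26	34	14	4	13	19	18	25	3	14	23
myosin_heavy_chain_1_2x	114	105	78	117	18	155	71	130	42	116	180	120	44	94	106	124	95	26	61	143
myosin_heavy_chain_2a	188	101	83	118	38	108	59	144	42	114	164	119	31	76	86	142	102	22	68	130
myosin_heavy_chain_2b	131	113	78	111	33	127	72	152	44	112	194	93	58	70	95	149	93	15	50	147
myosin_light_chain_kinase	39	40	25	30	11	46	21	35	18	36	75	34	17	27	31	29	29	4	9	40
myosin_light_chain_phosphorylatable	10	13	5	7	2	9	4	16	4	15	16	11	4	9	11	8	7	3	5	10
tropomyosin_1	28	14	10	18	2	18	14	24	4	14	29	11	8	3	13	19	17	2	13	23
tropomyosin_2	23	12	18	20	3	20	7	16	3	23	29	16	11	11	15	11	15	4	7	20
troponin_c_1	15	7	7	6	1	19	8	12	2	5	21	6	7	9	6	10	5	2	2	11
troponin_c_2	16	3	0	8	3	12	5	13	7	10	20	13	3	7	7	12	7	1	2	11
troponin_i_1	15	8	4	7	3	17	4	18	3	13	20	16	3	11	7	11	9	0	2	16
troponin_i_2	17	11	4	6	5	14	8	12	1	14	16	12	7	4	11	13	12	3	4	8
troponin_t_1	13	9	6	16	1	17	11	22	8	16	23	17	8	18	13	17	11	3	14	19
troponin_t_2	16	19	10	15	1	23	13	23	4	19	27	17	13	12	16	19	15	2	10	14
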