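metabolite	fasting_mean	fasting_sd	post_absorptive_mean	post_absorptive_sd
glucose	5		7
palmitate	0.125		0.125
tetradecanoate	0.230		0.230
arginine	0.080	20	0.115	14
histidine	0.082	10	0.118	7
isoleucine	0.062	14	0.128	14
leucine	0.123	25	0.271	14
lysine	0.188	32	0.294	24
methionine	0.025	4	0.030	2
phenylalanine	0.057	9	0.068	4
threonine	0.140	33	0.182	13
tryptophan	0.044	7	0.036	3.6
valine	0.233	43	0.349	36
alanine	0.333	74	0.309	46
asparagine	0.041	10	0.045	2
aspartate	0.003	1	0.067	10
cysteine	0.052	11	0.093	10
glutamate	0.024	15	0.152	22
glutamine	0.586	84	0.541	25
glycine	0.230	52	0.281	33
proline	0.168	60	0.299	23
serine	0.114	19	0.175	11
tyrosine	0.059	12	0.092	9
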