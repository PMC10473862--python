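rsID	chrom	pos	ref	alt	significance	condition
rs121434442	2	32353150	C	T	pathogenic	hereditary spastic paraplegia
rs121908745	4	88535832	G	A	pathogenic	amyotrophic lateral sclerosis
rs429358	19	45411941	T	C	risk factor	Alzheimer disease
rs7794745	7	146489606	A	T	risk factor	autism susceptibility 15
rs2066844	16	50745926	C	T	pathogenic	Crohn disease
rs121913527	12	25398281	C	A	pathogenic	Noonan syndrome
rs104894421	13	108863559	C	T	pathogenic	LIG4 syndrome
rs104893877	4	90749321	G	A	pathogenic	Parkinson disease 1
rs1801133	1	11856378	G	A	likely pathogenic	homocystinuria
rs4988235	2	136608646	G	A	benign	lactase persistence
rs121909001	5	148826877	C	G	pathogenic	diastrophic dysplasia
rs28940579	14	28767631	A	C	pathogenic	spastic paraplegia 3A
rs121918101	17	48275363	C	A	pathogenic	osteogenesis imperfecta
rs80338939	13	20763612	G	A	pathogenic	nonsyndromic hearing loss
rs113993960	7	117199644	A	T	pathogenic	cystic fibrosis modifier
rs121909211	9	135781588	C	T	likely pathogenic	tuberous sclerosis 1
rs137852783	11	2186700	G	T	pathogenic	Beckwith-Wiedemann spectrum
rs121434568	21	36259324	C	G	pathogenic	ulcerative colitis susceptibility
rs104894748	6	26093141	C	G	pathogenic	hemochromatosis
rs74315403	20	4680404	G	A	pathogenic	Creutzfeldt-Jakob disease
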