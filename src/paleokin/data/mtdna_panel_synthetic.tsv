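rsID	chrom	pos	ref	alt	significance	condition
rs199476104	MT	3460	G	A	pathogenic	Leber hereditary optic neuropathy
rs199476112	MT	11778	G	A	pathogenic	Leber hereditary optic neuropathy
rs199476105	MT	14484	T	C	pathogenic	Leber hereditary optic neuropathy
rs199476118	MT	3243	A	G	pathogenic	MELAS syndrome
rs199476133	MT	8344	A	G	pathogenic	MERRF syndrome
rs199476135	MT	8993	T	G	pathogenic	NARP syndrome
rs199474657	MT	1555	A	G	pathogenic	aminoglycoside-induced deafness
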