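gene	novel_exon	chrom	start	end	classification	domain
SORCS3	20a	10	105244778	105244837	ORF	Lumenal
GRIA1	2a	5	153509750	153509806	PTC	Extracellular
XRN2	16a	20	21345834	21345887	PTC	None
XRN2	29a	20	21387308	21387371	PTC(<50nt)	Disordered
SLC30A9	6a	4	42028140	42028260	PTC	Helix
SLC30A9	9a	4	42059964	42060036	PTC	Cation efflux family
GRM3	2a	7	86776784	86777014	PTC	None
GRM3	3a	7	86832296	86832411	PTC	None
NEGR1	6a	1	71532866	71532907	ORF	None
NEGR1	6b	1	71587343	71587400	PTC(<50nt)	Transmembrane
RFTN2	1a	2	197654257	197654391	PTC	None
RFTN2	1b	2	197671542	197671664	PTC	None
RFTN2	6a	2	197616952	197617073	PTC	None
CNTN4	1a	3	2656485	2656587	PTC	None
PTK2B	3a	8	27318676	27318793	UTR	None
PTK2B	3a (short)	8	27318696	27318793	UTR	None
PTK2B	3b	8	27319918	27319985	UTR	None
CLCN3	1a	4	169630165	169630335	UTR	None
CLCN3	2a	4	169638597	169638742	PTC	Cytoplasmic
CLCN3	2b	4	169640168	169640208	PTC	Cytoplasmic
CLCN3	2c	4	169663527	169663617	PTC	Cytoplasmic
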