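roi_group	roi	n	ld_aep_awake	ld_aep_drowsy	ld_aep_asleep	ld_hg_awake	ld_hg_drowsy	ld_hg_asleep	gd_aep_awake	gd_aep_drowsy	gd_aep_asleep	gd_hg_awake	gd_hg_drowsy	gd_hg_asleep
auditory	HGPM	23	22	23	20	18	18	8	12	4	0	3	0	0
auditory	HGAL	13	13	12	9	5	5	2	6	3	2	2	0	1
auditory	PP	14	1	4	1	0	0	0	2	0	0	0	0	0
auditory	PT	22	18	18	9	8	7	2	3	0	0	2	0	0
auditory	STGM	16	10	11	1	1	5	0	10	0	0	1	0	0
auditory	STGP	44	30	27	7	7	10	0	7	0	0	7	0	0
auditory-related	MTGA	7	1	1	2	0	0	0	0	0	0	0	0	0
auditory-related	MTGM	34	9	16	3	0	0	0	3	0	0	1	0	0
auditory-related	MTGP	57	17	5	2	0	1	0	5	0	0	1	0	0
auditory-related	STGA	10	3	2	1	1	1	0	1	0	0	1	0	0
auditory-related	STS	33	12	14	7	1	0	0	4	1	0	2	0	0
auditory-related	AG	25	1	5	1	0	0	0	2	0	0	1	0	0
auditory-related	SMG	38	9	12	7	1	1	0	5	0	0	2	0	0
prefrontal	ACC	7	0	0	0	0	0	0	0	0	0	0	0	0
prefrontal	FP	14	0	0	0	0	0	0	2	0	0	0	0	0
prefrontal	IFGop	13	3	2	0	0	0	0	1	0	0	0	0	0
prefrontal	IFGor	6	0	0	0	0	0	0	0	0	0	0	0	0
prefrontal	IFGtr	33	3	2	0	0	0	0	3	2	0	1	0	0
prefrontal	MFG	48	3	3	2	1	0	1	6	0	0	0	0	0
prefrontal	OG	37	4	2	3	0	0	0	1	1	0	0	0	0
prefrontal	SFG	4	0	0	0	0	0	0	0	0	0	0	0	0
other	Amyg	10	2	0	0	0	0	0	2	0	0	1	0	0
other	Hipp	13	4	1	0	0	0	0	3	0	0	1	0	0
other	PHG	9	0	0	0	0	0	0	0	0	0	0	0	0
other	PostCG	21	6	5	2	0	0	0	3	1	0	0	0	0
other	PreCG	38	10	9	2	0	0	1	7	1	0	1	0	0
other	CingMA	5	0	0	0	0	0	0	1	0	0	1	0	0
other	CingMP	1	0	0	0	0	0	0	0	0	0	0	0	0
other	FG	19	1	1	0	0	0	0	0	0	0	0	0	0
other	GR	10	1	1	0	0	0	0	4	0	0	0	0	0
other	ITG	40	5	3	0	0	1	0	3	0	0	0	0	0
other	InsA	10	2	0	1	0	0	0	0	0	0	0	0	0
other	InsP	25	3	5	2	0	0	0	4	0	0	0	0	0
other	LingG	4	0	0	0	0	0	0	0	0	0	0	0	0
other	MOG	1	0	0	0	0	0	0	0	0	0	0	0	0
other	PMC	20	1	0	0	0	0	0	1	2	0	1	0	0
other	PreCun	2	0	0	0	0	0	0	0	0	0	1	0	0
other	SubCG	2	0	0	1	0	0	0	1	0	0	0	0	0
other	SubInn	3	0	0	0	0	0	0	0	0	0	0	0	0
other	TP	26	2	3	0	0	0	0	2	0	0	0	0	0
other	FOp	1	0	0	0	0	1	0	0	0	0	0	0	0
other	POp	6	1	3	0	0	1	0	2	0	0	0	0	0
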