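roi_group	roi	n	ld_aep_awake	ld_aep_sedated	ld_aep_unresponsive	ld_hg_awake	ld_hg_sedated	ld_hg_unresponsive	gd_aep_awake	gd_aep_sedated	gd_aep_unresponsive	gd_hg_awake	gd_hg_sedated	gd_hg_unresponsive
auditory	HGPM	35	32	28	24	20	15	11	10	2	0	1	0	0
auditory	HGAL	5	4	3	1	2	1	0	2	2	0	0	0	0
auditory	PP	11	10	7	5	0	0	0	8	1	0	0	0	0
auditory	PT	18	14	15	15	6	9	8	8	3	0	0	0	0
auditory	STGM	39	18	10	7	10	6	9	4	1	0	5	0	0
auditory	STGP	23	11	5	3	8	2	2	1	0	0	3	0	0
auditory-related	MTGA	25	5	1	0	0	0	0	3	0	0	0	0	0
auditory-related	MTGM	47	8	0	0	1	0	1	3	2	0	0	0	0
auditory-related	MTGP	34	5	2	0	0	0	0	4	0	0	1	0	0
auditory-related	STGA	6	3	2	1	0	0	0	2	1	0	0	0	0
auditory-related	STS	31	21	10	2	0	1	1	14	6	0	0	0	0
auditory-related	AG	16	1	1	0	0	0	1	1	0	0	0	0	0
auditory-related	SMG	37	6	4	0	2	1	1	3	1	0	2	0	0
prefrontal	ACC	13	2	1	1	0	0	0	5	4	0	0	0	0
prefrontal	IFGop	14	6	5	0	0	0	0	5	0	0	0	0	0
prefrontal	IFGor	6	3	1	2	0	0	0	2	0	0	0	0	0
prefrontal	IFGtr	43	17	10	0	0	1	1	19	11	0	1	0	0
prefrontal	MFG	52	12	4	0	0	0	0	19	8	0	0	0	0
prefrontal	OG	42	9	3	0	0	0	1	12	0	0	0	0	0
prefrontal	SFG	20	3	0	0	0	0	0	6	0	0	0	0	0
other	Amyg	23	5	1	0	0	0	0	5	1	0	0	0	0
other	Hipp	29	13	2	0	0	0	0	8	1	0	0	0	0
other	PHG	8	1	0	0	0	0	0	1	0	0	0	0	0
other	ParaCL	2	0	0	0	0	0	0	0	0	0	0	0	0
other	PostCG	39	20	16	14	5	6	4	8	3	0	3	2	0
other	PreCG	69	19	9	4	0	1	0	11	1	0	4	0	0
other	Caud	7	6	0	0	0	0	0	0	0	0	0	0	0
other	CingMA	8	1	0	0	0	0	0	3	3	0	0	0	0
other	CingMP	6	1	0	0	0	0	0	0	0	0	0	0	0
other	CingPD	4	0	0	0	0	0	0	0	0	0	0	0	0
other	CingPV	1	0	0	0	0	0	0	1	0	0	0	0	0
other	FG	15	2	0	0	0	0	0	3	0	0	0	0	1
other	GR	10	1	0	1	0	0	0	2	0	0	0	0	0
other	IPS	3	0	0	0	0	0	0	0	0	0	1	0	0
other	ITG	17	1	0	0	0	0	0	1	0	0	0	0	0
other	InsA	17	5	4	1	0	0	0	9	5	0	0	0	0
other	InsP	19	13	11	5	2	1	0	10	6	0	0	0	0
other	LingG	4	1	0	0	0	0	0	0	1	0	0	0	0
other	MOG	2	0	0	0	0	0	0	0	0	0	0	0	0
other	PMC	24	2	2	0	0	0	0	1	1	0	0	0	0
other	PreCun	3	0	0	0	0	0	0	1	0	0	0	0	0
other	SubCG	2	0	0	1	0	0	0	0	0	0	0	0	0
other	TP	28	4	0	0	0	0	0	5	0	0	0	0	0
other	FOp	2	0	0	0	0	0	0	0	0	0	0	0	0
other	POp	2	0	0	0	0	0	0	2	0	0	0	0	0
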