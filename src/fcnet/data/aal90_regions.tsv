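index	label	abbreviation	hemisphere	name
1	PreCG.L	PreCG	left	Precental gyrus
2	PreCG.R	PreCG	right	Precental gyrus
3	SFGdor.L	SFGdor	left	Superior frontal gyrus, dorsolateral
4	SFGdor.R	SFGdor	right	Superior frontal gyrus, dorsolateral
5	ORBsup.L	ORBsup	left	Superior frontal gyrus, orbital part
6	ORBsup.R	ORBsup	right	Superior frontal gyrus, orbital part
7	MFG.L	MFG	left	Middle frontal gyrus
8	MFG.R	MFG	right	Middle frontal gyrus
9	ORBmid.L	ORBmid	left	Middle frontal gyrus, orbital part
10	ORBmid.R	ORBmid	right	Middle frontal gyrus, orbital part
11	IFGoperc.L	IFGoperc	left	Inferior frontal gyrus, opercular part
12	IFGoperc.R	IFGoperc	right	Inferior frontal gyrus, opercular part
13	IFGtriang.L	IFGtriang	left	Inferior frontal gyrus, triangular part
14	IFGtriang.R	IFGtriang	right	Inferior frontal gyrus, triangular part
15	ORBinf.L	ORBinf	left	Inferior frontal gyrus, orbital part
16	ORBinf.R	ORBinf	right	Inferior frontal gyrus, orbital part
17	ROL.L	ROL	left	Rolandic operculum
18	ROL.R	ROL	right	Rolandic operculum
19	SMA.L	SMA	left	Supplementary motor area
20	SMA.R	SMA	right	Supplementary motor area
21	OLF.L	OLF	left	Olfactory cortex
22	OLF.R	OLF	right	Olfactory cortex
23	SFGmed.L	SFGmed	left	Superior frontal gyrus, media
24	SFGmed.R	SFGmed	right	Superior frontal gyrus, media
25	ORBsupmed.L	ORBsupmed	left	Superior frontal gyrus, medial orbital
26	ORBsupmed.R	ORBsupmed	right	Superior frontal gyrus, medial orbital
27	REC.L	REC	left	Gyrus rectus
28	REC.R	REC	right	Gyrus rectus
29	INS.L	INS	left	Insula
30	INS.R	INS	right	Insula
31	ACG.L	ACG	left	Anterior cingulate and paracingulate gyri
32	ACG.R	ACG	right	Anterior cingulate and paracingulate gyri
33	DCG.L	DCG	left	Median cingulate and paracingulate gyri
34	DCG.R	DCG	right	Median cingulate and paracingulate gyri
35	PCG.L	PCG	left	Posterior cingulate gyrus
36	PCG.R	PCG	right	Posterior cingulate gyrus
37	HIP.L	HIP	left	Hippocampus
38	HIP.R	HIP	right	Hippocampus
39	PHG.L	PHG	left	Parahippocampal gyrus
40	PHG.R	PHG	right	Parahippocampal gyrus
41	AMYG.L	AMYG	left	Amygdala
42	AMYG.R	AMYG	right	Amygdala
43	CAL.L	CAL	left	Calcarine fissure and surrounding cortex
44	CAL.R	CAL	right	Calcarine fissure and surrounding cortex
45	CUN.L	CUN	left	Cuneus
46	CUN.R	CUN	right	Cuneus
47	LING.L	LING	left	Lingual gyrus
48	LING.R	LING	right	Lingual gyrus
49	SOG.L	SOG	left	Superior occipital gyrus
50	SOG.R	SOG	right	Superior occipital gyrus
51	MOG.L	MOG	left	Middle occipital gyrus
52	MOG.R	MOG	right	Middle occipital gyrus
53	IOG.L	IOG	left	Inferior occipital gyrus
54	IOG.R	IOG	right	Inferior occipital gyrus
55	FFG.L	FFG	left	Fusiform gyrus
56	FFG.R	FFG	right	Fusiform gyrus
57	PoCG.L	PoCG	left	Postcentral gyrus
58	PoCG.R	PoCG	right	Postcentral gyrus
59	SPG.L	SPG	left	Superior parietal gyrus
60	SPG.R	SPG	right	Superior parietal gyrus
61	IPL.L	IPL	left	Inferior parietal, but supramarginal and angular gyri
62	IPL.R	IPL	right	Inferior parietal, but supramarginal and angular gyri
63	SMG.L	SMG	left	Supramarginal gyrus
64	SMG.R	SMG	right	Supramarginal gyrus
65	AMG.L	AMG	left	Angular gyrus
66	AMG.R	AMG	right	Angular gyrus
67	PCUN.L	PCUN	left	Precuneus
68	PCUN.R	PCUN	right	Precuneus
69	PCL.L	PCL	left	Paracentral lobule
70	PCL.R	PCL	right	Paracentral lobule
71	CAU.L	CAU	left	Caudate nucleus
72	CAU.R	CAU	right	Caudate nucleus
73	PUT.L	PUT	left	Lenticular nucleus, putamen
74	PUT.R	PUT	right	Lenticular nucleus, putamen
75	PAL.L	PAL	left	Lenticular nucleus, pallidum
76	PAL.R	PAL	right	Lenticular nucleus, pallidum
77	THA.L	THA	left	Thalamus
78	THA.R	THA	right	Thalamus
79	HES.L	HES	left	Heschl gyrus
80	HES.R	HES	right	Heschl gyrus
81	STG.L	STG	left	Superior temporal gyrus
82	STG.R	STG	right	Superior temporal gyrus
83	TPOsup.L	TPOsup	left	Temporal pole: superior temporal gyrus
84	TPOsup.R	TPOsup	right	Temporal pole: superior temporal gyrus
85	MTG.L	MTG	left	Middle temporal gyrus
86	MTG.R	MTG	right	Middle temporal gyrus
87	TPOmid.L	TPOmid	left	Temporal pole: middle temporal gyrus
88	TPOmid.R	TPOmid	right	Temporal pole: middle temporal gyrus
89	ITG.L	ITG	left	Inferior temporal gyrus
90	ITG.R	ITG	right	Inferior temporal gyrus
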