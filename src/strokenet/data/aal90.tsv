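region_id	name	abbreviation	hemisphere	volume_mm3
2001	Precentral gyrus	PreCG.L	L	9715.8
2002	Precentral gyrus	PreCG.R	R	8927.7
2101	Superior frontal gyrus (dorsolateral)	SFGdor.L	L	22120.8
2102	Superior frontal gyrus (dorsolateral)	SFGdor.R	R	23932.8
2111	Superior frontal gyrus (orbital)	ORBsup.L	L	7676.9
2112	Superior frontal gyrus (orbital)	ORBsup.R	R	7663.4
2201	Middle frontal gyrus	MFG.L	L	6745.3
2202	Middle frontal gyrus	MFG.R	R	6956.1
2211	Middle frontal gyrus (orbital)	ORBmid.L	L	15077.3
2212	Middle frontal gyrus (orbital)	ORBmid.R	R	15508.7
2301	Inferior frontal gyrus (opercular)	IFGoperc.L	L	9512.6
2302	Inferior frontal gyrus (opercular)	IFGoperc.R	R	9023.3
2311	Inferior frontal gyrus (triangular)	IFGtriang.L	L	12030.7
2312	Inferior frontal gyrus (triangular)	IFGtriang.R	R	12330.7
2321	Inferior frontal gyrus (orbital)	ORBinf.L	L	10510.7
2322	Inferior frontal gyrus (orbital)	ORBinf.R	R	11519.0
2331	Rolandic operculum	ROL.L	L	7526.8
2332	Rolandic operculum	ROL.R	R	6911.4
2401	Supplementary motor area	SMA.L	L	10462.2
2402	Supplementary motor area	SMA.R	R	11042.8
2501	Olfactory cortex	OLF.L	L	14053.2
2502	Olfactory cortex	OLF.R	R	15533.0
2601	Superior frontal gyrus (medial)	SFGmed.L	L	14362.4
2602	Superior frontal gyrus (medial)	SFGmed.R	R	14767.7
2611	Superior frontal gyrus (medial orbital)	ORBsupmed.L	L	18813.0
2612	Superior frontal gyrus (medial orbital)	ORBsupmed.R	R	18122.6
2701	Rectus gyrus	REC.L	L	15049.8
2702	Rectus gyrus	REC.R	R	14068.8
3001	Insula	INS.L	L	25677.6
3002	Insula	INS.R	R	23786.8
4001	Anterior cingulate gyrus	ACG.L	L	7465.3
4002	Anterior cingulate gyrus	ACG.R	R	8102.0
4011	Median cingulate gyrus	MCG.L	L	7086.1
4012	Median cingulate gyrus	MCG.R	R	7143.3
4021	Posterior cingulate gyrus	PCG.L	L	10731.2
4022	Posterior cingulate gyrus	PCG.R	R	11423.1
4101	Hippocampus	HIP.L	L	12420.0
4102	Hippocampus	HIP.R	R	13633.7
4111	Parahippocampal gyrus	PHG.L	L	4313.2
4112	Parahippocampal gyrus	PHG.R	R	4621.7
4201	Amygdala	AMYG.L	L	12601.2
4202	Amygdala	AMYG.R	R	13822.2
5001	Calcarine cortex	CAL.L	L	14106.4
5002	Calcarine cortex	CAL.R	R	13404.0
5011	Cuneus	CUN.L	L	18346.8
5012	Cuneus	CUN.R	R	16936.1
5021	Lingual gyrus	LING.L	L	13524.8
5022	Lingual gyrus	LING.R	R	12833.4
5101	Superior occipital gyrus	SOG.L	L	7866.5
5102	Superior occipital gyrus	SOG.R	R	7576.6
5201	Middle occipital gyrus	MOG.L	L	7868.7
5202	Middle occipital gyrus	MOG.R	R	7853.2
5301	Inferior occipital gyrus	IOG.L	L	8352.1
5302	Inferior occipital gyrus	IOG.R	R	7865.2
5401	Fusiform gyrus	FFG.L	L	14760.9
5402	Fusiform gyrus	FFG.R	R	15435.0
6001	Postcentral gyrus	PoCG.L	L	19734.0
6002	Postcentral gyrus	PoCG.R	R	20165.3
6101	Superior parietal gyrus	SPG.L	L	14731.4
6102	Superior parietal gyrus	SPG.R	R	14119.1
6201	Inferior parietal gyrus	IPG.L	L	6603.6
6202	Inferior parietal gyrus	IPG.R	R	6982.0
6211	Supramarginal gyrus	SMG.L	L	7837.1
6212	Supramarginal gyrus	SMG.R	R	7596.7
6221	Angular gyrus	ANG.L	L	11859.0
6222	Angular gyrus	ANG.R	R	12989.8
6301	Precuneus	PCUN.L	L	19318.8
6302	Precuneus	PCUN.R	R	21096.4
6401	Paracentral lobule	PCL.L	L	7321.4
6402	Paracentral lobule	PCL.R	R	7217.2
7001	Caudate	CAU.L	L	7860.0
7002	Caudate	CAU.R	R	8416.8
7011	Putamen	PUT.L	L	6991.8
7012	Putamen	PUT.R	R	7097.0
7021	Pallidum	PAL.L	L	6271.5
7022	Pallidum	PAL.R	R	6319.3
7101	Thalamus	THA.L	L	12630.8
7102	Thalamus	THA.R	R	11997.7
8101	Heschl gyrus	HES.L	L	7320.1
8102	Heschl gyrus	HES.R	R	6976.8
8111	Superior temporal gyrus	STG.L	L	13261.1
8112	Superior temporal gyrus	STG.R	R	13126.9
8121	Temporal pole (superior)	TPOsup.L	L	7460.3
8122	Temporal pole (superior)	TPOsup.R	R	7804.4
8201	Middle temporal gyrus	MTG.L	L	13410.0
8202	Middle temporal gyrus	MTG.R	R	13822.2
8211	Temporal pole (middle)	TPOmid.L	L	19907.3
8212	Temporal pole (middle)	TPOmid.R	R	18243.9
8301	Inferior temporal gyrus	ITG.L	L	15974.6
8302	Inferior temporal gyrus	ITG.R	R	15111.5
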