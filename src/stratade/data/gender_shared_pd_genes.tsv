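gene	genbank_id	allN_allPD	fN_fPD	mN_mPD	mN_fN	mPD_fPD
ATP5G3	NM_001689	-2.25	-2.17	-2.94	0	0
ATP6V1E1	NM_001696	-3.57	-4.76	-3.23	0	0
CHRNA4	NM_000744	1.25	1.4	1.22	0	0
CLTC	NM_004859	-1.33	-5.56	-3.12	0	0
COX7C	NM_001867	-2.90	-2.56	-3.64	0	0
DRD2	NM_016574	1.26	1.33	1.32	0	0
NDUFB2	NM_004546	-3.39	-2.22	-3.70	0	0
PRKACB	NM_207578	-2.44	1.35	-2.70	0	0
SLC35A1	NM_006416	-1.49	-1.79	-1.37	0	0
SLC6A1	NM_003042	-1.67	-1.85	-1.56	0	0
TIMM44	NM_006351	0	-1.49	1.26	0	0
UQCRH	NM_006004	-2.94	-3.45	-2.63	0	0
ZNF606	NM_025027	1.31	1.4	1.27	0	0
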